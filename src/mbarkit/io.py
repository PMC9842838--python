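"""Tabular file readers/writers, replica demultiplexing, and the pipeline.

The interchange contract is plain delimited text: collective-variable files
(column 1 a sample index, remaining columns CV values, no header), energy
tables (header row naming columns, column 1 a sample index), per-state
neighbor-energy tables (columns ``u_prev``, ``u_self``, ``u_next``), and a
state table (one state per row, mode-specific fields).  Engine-specific log
formats are deliberately not parsed.  Numeric output is written at full
precision (the shortest decimal that round-trips the float64), so reruns can
be compared bit-for-bit, and every output
file carries a header with the package version, seed, and a hash of the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigError, InputError
from .accumulate import NeighborEnergySet, estimate_chain
from .constants import beta_from_temperature
from .reweight import compute_pmf, target_free_energy
from .solver import solve_mbar
from .states import Mode, SampleSet, ThermoState, build_reduced_matrix
from .uncertainty import ResamplingPlan

__all__ = [
    "read_cv_file",
    "write_cv_file",
    "read_energy_file",
    "write_energy_file",
    "read_neighbor_file",
    "read_state_table",
    "demux_replicas",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

_SPLIT = re.compile(r"[,\s]+")


def _fmt(v) -> str:
    """Shortest decimal that round-trips the float64 exactly."""
    return repr(float(v))


def _parse_rows(path):
    rows, numbers = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, _SPLIT.split(line)))
    if not rows:
        raise InputError(f"{path}: no data rows (empty or comments only)")
    width = len(rows[0][1])
    for lineno, fields in rows:
        if len(fields) != width:
            raise InputError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {width})"
            )
    return rows, width


def read_cv_file(path):
    """Read a collective-variable trajectory file.

    Whitespace- or comma-delimited; column 1 is the sample index, columns
    2..d+1 the CV values; ``#`` comment lines are skipped.  Returns
    (index array, cv array of shape (N, d)).
    """
    rows, width = _parse_rows(path)
    if width < 2:
        raise InputError(f"{path}: need an index column plus >= 1 CV column")
    try:
        data = np.array([[float(v) for v in fields] for _, fields in rows])
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric field ({exc})") from None
    return data[:, 0], data[:, 1:]


def write_cv_file(path, cv, index=None, header_lines=()):
    """Write a CV file in the format :func:`read_cv_file` reads back."""
    cv = np.asarray(cv, dtype=float)
    if cv.ndim == 1:
        cv = cv[:, None]
    if index is None:
        index = np.arange(1, len(cv) + 1)
    out = np.column_stack([np.asarray(index, dtype=float), cv])
    header = "".join(f"# {line}\n" for line in header_lines)
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_energy_file(path) -> pd.DataFrame:
    """Read an energy table: header row of names, column 1 a sample index.

    Returns a DataFrame of the named energy columns (kcal/mol), with the
    sample index as the frame index.
    """
    rows, width = _parse_rows(path)
    header_line, header = rows[0]
    try:
        [float(v) for v in header]
    except ValueError:
        pass
    else:
        raise InputError(
            f"{path}:{header_line}: expected a header row naming columns"
        )
    if width < 2:
        raise InputError(f"{path}: need an index column plus >= 1 energy column")
    try:
        data = np.array([[float(v) for v in fields] for _, fields in rows[1:]])
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric field ({exc})") from None
    if data.size == 0:
        raise InputError(f"{path}: header but no data rows")
    frame = pd.DataFrame(data[:, 1:], columns=header[1:])
    frame.index = data[:, 0]
    return frame


def write_energy_file(path, frame: pd.DataFrame, header_lines=()):
    header = "".join(f"# {line}\n" for line in header_lines)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("index " + " ".join(frame.columns) + "\n")
        out = np.column_stack([np.asarray(frame.index, dtype=float),
                               frame.to_numpy(dtype=float)])
        for row in out:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_neighbor_file(path, state_index: int) -> NeighborEnergySet:
    """Read one lambda state's neighbor reduced-energy table.

    Header names any of ``u_prev``, ``u_self``, ``u_next``; ``u_self`` is
    required, the ends of the chain omit one neighbor column.
    """
    frame = read_energy_file(path)
    if "u_self" not in frame.columns:
        raise InputError(f"{path}: missing required column 'u_self'")
    return NeighborEnergySet(
        state_index=state_index,
        u_self=frame["u_self"].to_numpy(),
        u_prev=frame["u_prev"].to_numpy() if "u_prev" in frame.columns else None,
        u_next=frame["u_next"].to_numpy() if "u_next" in frame.columns else None,
    )


def read_state_table(path, mode, *, half_spring=False) -> list[ThermoState]:
    """Read the per-state parameter table (CSV/whitespace with header).

    Recognized columns: ``temperature`` (K) or ``beta``; ``center`` /
    ``spring_k`` / ``period`` for restraints; ``lambda`` for accumulation;
    ``energy_column`` for full mode; ``pressure``.
    """
    mode = Mode(mode)
    rows, _ = _parse_rows(path)
    header = rows[0][1]
    records = [dict(zip(header, fields)) for _, fields in rows[1:]]
    if not records:
        raise InputError(f"{path}: no state rows")
    states = []
    for rec in records:
        if "beta" in rec:
            beta = float(rec["beta"])
        elif "temperature" in rec:
            beta = beta_from_temperature(float(rec["temperature"]))
        else:
            raise ConfigError(
                f"{path}: each state needs 'beta' or 'temperature'"
            )
        kwargs = {}
        if "center" in rec:
            kwargs["z_ref"] = [float(rec["center"])]
        if "spring_k" in rec:
            k = float(rec["spring_k"])
            kwargs["spring_k"] = [0.5 * k if half_spring else k]
        if "period" in rec and rec["period"].lower() not in ("", "none", "nan"):
            kwargs["periodic"] = [float(rec["period"])]
        if "lambda" in rec:
            kwargs["lambda_value"] = float(rec["lambda"])
        if "energy_column" in rec:
            kwargs["energy_column"] = rec["energy_column"]
        if "pressure" in rec:
            kwargs["pressure"] = float(rec["pressure"])
        states.append(ThermoState(mode=mode, beta=beta, **kwargs))
    return states


def demux_replicas(series, param_index, samples_per_period=None):
    """Re-sort per-replica series into per-parameter series.

    ``series`` is a list of per-replica 1-D arrays (equal length);
    ``param_index`` has shape (n_periods, n_replicas) and gives, for each
    exchange period, which parameter (temperature/lambda) each replica held.
    Every period row must be a permutation of 0..R-1.  Sample n of the
    returned parameter-i series comes from the replica that held parameter i
    during n's period.
    """
    arrays = [np.asarray(s) for s in series]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise InputError("all replica series must have equal length")
    total = lengths.pop()
    pmap = np.asarray(param_index, dtype=np.int64)
    if pmap.ndim != 2 or pmap.shape[1] != len(arrays):
        raise InputError(
            f"param_index must be (n_periods, n_replicas={len(arrays)})"
        )
    n_periods = pmap.shape[0]
    for p in range(n_periods):
        if sorted(pmap[p]) != list(range(len(arrays))):
            raise InputError(f"period {p}: param_index row is not a permutation")
    if samples_per_period is None:
        if total % n_periods:
            raise InputError(
                f"series length {total} not divisible by {n_periods} periods"
            )
        samples_per_period = total // n_periods
    elif samples_per_period * n_periods != total:
        raise InputError("samples_per_period * n_periods must equal series length")

    stacked = np.stack(arrays)  # (R, total)
    out = np.empty_like(stacked)
    for p in range(n_periods):
        sl = slice(p * samples_per_period, (p + 1) * samples_per_period)
        # replica r holds parameter pmap[p, r] during this period
        out[pmap[p], sl] = stacked[:, sl]
    return [out[i] for i in range(len(arrays))]


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    mode: str
    output_dir: str
    state_table: str | None = None
    cv_files: list[str] = field(default_factory=list)
    energy_files: list[str] = field(default_factory=list)
    neighbor_files: list[str] = field(default_factory=list)
    temperatures: list[float] | None = None
    target_temperature: float | None = None
    target_energy_column: str | None = None
    bin_min: float | None = None
    bin_max: float | None = None
    n_bins: int | None = None
    tolerance: float = 1e-8
    resampling: str = "block"
    n_blocks: int = 10
    n_replicates: int = 50
    half_spring: bool = False
    reduced: bool = False
    seed: int = 0

    def plan(self) -> ResamplingPlan:
        return ResamplingPlan(
            method=self.resampling,
            n_blocks=self.n_blocks,
            n_replicates=self.n_replicates,
            seed=self.seed,
        )

    def validate(self):
        mode = self.mode
        if mode not in ("restraint", "scaling", "accumulation", "full"):
            raise ConfigError(f"unknown mode {mode!r}")
        if mode == "restraint":
            _require(self.state_table, "state_table", mode)
            _require(self.cv_files, "cv_files", mode)
        elif mode == "scaling":
            _require(self.energy_files, "energy_files", mode)
            if not self.reduced and not self.temperatures:
                raise ConfigError(
                    "scaling mode requires 'temperatures' (or --reduced input)"
                )
            if self.temperatures and len(self.temperatures) != len(self.energy_files):
                raise ConfigError(
                    "one temperature per energy file is required"
                )
        elif mode == "accumulation":
            _require(self.neighbor_files, "neighbor_files", mode)
        elif mode == "full":
            _require(self.state_table, "state_table", mode)
            _require(self.energy_files, "energy_files", mode)
        for p in [self.state_table, *self.cv_files, *self.energy_files,
                  *self.neighbor_files]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"referenced path does not exist: {p}")

    def bin_edges(self):
        if self.bin_min is None or self.bin_max is None or self.n_bins is None:
            return None
        return np.linspace(self.bin_min, self.bin_max, self.n_bins + 1)

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where its results land
        fields = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(value, name, mode):
    if not value:
        raise ConfigError(f"{mode} mode requires config field '{name}'")


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration, applying keyword overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def _output_header(config: RunConfig):
    from . import __version__

    return [
        f"mbarkit {__version__}",
        f"seed {config.seed}",
        f"config {config.config_hash()}",
    ]


def _write_csv(path, frame: pd.DataFrame, header_lines):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, float_format=_fmt)


def run_pipeline(config: RunConfig) -> dict:
    """Dispatch one configured run: build inputs, solve, reweight, write.

    Writes ``free_energy.json`` plus, depending on mode, ``pmf.csv`` or
    ``chain.csv`` into the output directory.  On any stage failure the
    partially written outputs are removed and the error is re-raised with
    the stage name.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "setup"
    try:
        if config.mode == "accumulation":
            stage = "accumulate"
            sets = [
                read_neighbor_file(p, i)
                for i, p in enumerate(config.neighbor_files)
            ]
            chain = estimate_chain(sets, plan=config.plan())
            stage = "write"
            chain_path = out_dir / "chain.csv"
            _write_csv(chain_path, chain.to_frame(), _output_header(config))
            written.append(chain_path)
            report = {
                "mode": config.mode,
                "total_delta_f": chain.total,
                "total_se": chain.total_se,
                "cumulative": chain.cumulative.tolist(),
            }
        else:
            stage = "build"
            matrix, states, cv, u_target = _build_inputs(config)
            stage = "solve"
            result = solve_mbar(matrix, tolerance=config.tolerance)
            report = result.to_report()
            report["mode"] = config.mode
            if u_target is not None:
                report["f_target"] = target_free_energy(result, u_target)
            edges = config.bin_edges()
            if edges is not None and cv is not None and u_target is not None:
                stage = "pmf"
                profile = compute_pmf(
                    result, u_target, cv, edges,
                    matrix=matrix, plan=config.plan(),
                )
                stage = "write"
                pmf_path = out_dir / "pmf.csv"
                _write_csv(pmf_path, profile.to_frame(), _output_header(config))
                written.append(pmf_path)
        stage = "write"
        from . import __version__

        report["version"] = __version__
        report["seed"] = config.seed
        report["config_hash"] = config.config_hash()
        report_path = out_dir / "free_energy.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
        written.append(report_path)
        return report
    except Exception as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _build_inputs(config: RunConfig):
    """Assemble (matrix, states, pooled cv, pooled u_target) for one mode."""
    if config.mode == "restraint":
        states = read_state_table(
            config.state_table, Mode.RESTRAINT, half_spring=config.half_spring
        )
        if len(config.cv_files) != len(states):
            raise ConfigError(
                f"{len(config.cv_files)} CV files for {len(states)} states"
            )
        samplesets = []
        for j, p in enumerate(config.cv_files):
            _, cv = read_cv_file(p)
            samplesets.append(SampleSet(origin_state=j, cv=cv))
        matrix = build_reduced_matrix(states, samplesets)
        cv = np.concatenate([s.cv for s in samplesets])
        u_target = np.zeros(matrix.n_total)  # unrestrained ensemble
        return matrix, states, cv, u_target

    if config.mode == "scaling":
        frames = [read_energy_file(p) for p in config.energy_files]
        if config.reduced:
            betas = [1.0] * len(frames)
        else:
            betas = [beta_from_temperature(t) for t in config.temperatures]
        states = [ThermoState(mode=Mode.SCALING, beta=b) for b in betas]
        samplesets = []
        cv_parts = []
        for j, frame in enumerate(frames):
            if "U_system" not in frame.columns:
                raise ConfigError(
                    f"{config.energy_files[j]}: scaling mode requires a "
                    "'U_system' column"
                )
            samplesets.append(
                SampleSet(origin_state=j, energies=frame[["U_system"]])
            )
            if config.cv_files:
                _, cv = read_cv_file(config.cv_files[j])
                cv_parts.append(cv)
        matrix = build_reduced_matrix(states, samplesets)
        target_beta = (
            betas[0]
            if config.target_temperature is None
            else beta_from_temperature(config.target_temperature)
        )
        pooled_u = np.concatenate(
            [s.energies["U_system"].to_numpy() for s in samplesets]
        )
        u_target = target_beta * pooled_u
        cv = np.concatenate(cv_parts) if cv_parts else None
        return matrix, states, cv, u_target

    # full mode
    states = read_state_table(
        config.state_table, Mode.FULL, half_spring=config.half_spring
    )
    frames = [read_energy_file(p) for p in config.energy_files]
    if len(frames) != len(states):
        raise ConfigError(
            f"{len(frames)} energy files for {len(states)} states"
        )
    samplesets = []
    cv_parts = []
    for j, frame in enumerate(frames):
        cv = None
        if config.cv_files:
            _, cv = read_cv_file(config.cv_files[j])
            cv_parts.append(cv)
        samplesets.append(SampleSet(origin_state=j, cv=cv, energies=frame))
    matrix = build_reduced_matrix(states, samplesets)
    # target: a chosen energy column (e.g. the high-level surface) without
    # any restraint; defaults to the first state's column
    target_state = ThermoState(
        mode=Mode.FULL, beta=states[0].beta,
        energy_column=config.target_energy_column or states[0].energy_column,
    )
    from .states import reduce_potential

    u_target = np.concatenate(
        [reduce_potential(target_state, s) for s in samplesets]
    )
    cv = np.concatenate(cv_parts) if cv_parts else None
    return matrix, states, cv, u_target
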
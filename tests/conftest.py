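"""Shared synthetic study fixtures.

The heavier datasets (umbrella ladder, temperature ladder, alchemical chain,
dual-level windows) are generated once per session and shared between the
module tests and the acceptance suite.  All seeds are fixed.
"""

import numpy as np
import pytest

import mbarkit as mk
from mbarkit import synthetic as syn

# Frozen umbrella study: double-well landscape, 21 windows spanning the
# region the ladder is designed to resolve, springs sized so k*spacing
# exceeds the landscape gradient at the edges, stride long enough that kept
# samples are effectively uncorrelated.
UMBRELLA = dict(
    height=3.0,
    beta=1.0,
    n_windows=21,
    z_min=-1.4,
    z_max=1.4,
    spring_k=25.0,
    n_per_window=2000,
    step_size=0.3,
    stride=20,
    seed=0,
)
UMBRELLA_EDGES = np.linspace(-1.3, 1.3, 25)

# Frozen temperature-ladder study: tilted double-well, four temperatures.
TREMD = dict(
    height=4.0,
    tilt=0.5,
    betas=(1.0, 0.8, 0.64, 0.51),
    n_per_state=6000,
    n_reference=60000,
    step_size=0.6,
    stride=20,
    seed=0,
)
TREMD_EDGES = np.linspace(-1.4, 1.4, 25)

# Frozen alchemical chain: harmonic endpoints, 11 lambda states.
FEP = dict(
    k=1.0,
    shift=1.5,
    offset=2.0,
    n_lambda=11,
    beta=1.0,
    n_per_state=2000,
    seed=2,
)

# Frozen dual-level study: low-level double-well plus a 1 kT sinusoidal
# correction on the high-level surface, same window ladder as UMBRELLA.
DUAL = dict(correction_kt=1.0, wavenumber=2.5, seed=0)


def umbrella_centers():
    return np.linspace(UMBRELLA["z_min"], UMBRELLA["z_max"],
                       UMBRELLA["n_windows"])


def align(a, b, mask=None):
    """Difference of two profiles after removing the arbitrary gauge offset."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if mask is not None:
        d = d[mask]
    return d - np.nanmean(d)


@pytest.fixture(scope="session")
def umbrella_study():
    pot = syn.double_well(height=UMBRELLA["height"])
    centers = umbrella_centers()
    data = syn.gen_umbrella_windows(
        pot, centers, UMBRELLA["spring_k"], UMBRELLA["beta"],
        UMBRELLA["n_per_window"], seed=UMBRELLA["seed"],
        step_size=UMBRELLA["step_size"], stride=UMBRELLA["stride"],
    )
    states = [
        mk.ThermoState(mode="restraint", beta=UMBRELLA["beta"],
                       spring_k=[UMBRELLA["spring_k"]], z_ref=[c])
        for c in centers
    ]
    sets = [mk.SampleSet(origin_state=i, cv=t)
            for i, t in enumerate(data.trajectories)]
    matrix = mk.build_reduced_matrix(states, sets)
    result = mk.solve_mbar(matrix)
    return {
        "potential": pot,
        "data": data,
        "states": states,
        "matrix": matrix,
        "result": result,
        "cv": np.concatenate(data.trajectories),
    }


@pytest.fixture(scope="session")
def tremd_study():
    pot = syn.double_well(height=TREMD["height"], tilt=TREMD["tilt"])
    betas = np.asarray(TREMD["betas"])
    data = syn.gen_temperature_ladder(
        pot, betas, TREMD["n_per_state"], seed=TREMD["seed"],
        step_size=TREMD["step_size"], stride=TREMD["stride"],
    )
    states = [mk.ThermoState(mode="scaling", beta=b) for b in betas]
    sets = [
        mk.SampleSet(origin_state=i, energies={"U_system": e})
        for i, e in enumerate(data.energies)
    ]
    matrix = mk.build_reduced_matrix(states, sets)
    result = mk.solve_mbar(matrix)
    reference, _ = syn.mcmc_sample(
        pot, betas[0], TREMD["n_reference"],
        step_size=TREMD["step_size"], stride=TREMD["stride"],
        seed=TREMD["seed"] + 1000,
    )
    return {
        "potential": pot,
        "betas": betas,
        "data": data,
        "matrix": matrix,
        "result": result,
        "cv": np.concatenate(data.trajectories),
        "u_pooled": np.concatenate(data.energies),
        "reference": reference,
    }


@pytest.fixture(scope="session")
def fep_study():
    data = syn.gen_fep_chain(
        syn.harmonic(k=FEP["k"], center=0.0),
        syn.harmonic(k=FEP["k"], center=FEP["shift"], offset=FEP["offset"]),
        np.linspace(0.0, 1.0, FEP["n_lambda"]),
        FEP["beta"], FEP["n_per_state"], seed=FEP["seed"],
    )
    return data


@pytest.fixture(scope="session")
def dual_level_study():
    ll = syn.double_well(height=UMBRELLA["height"])
    grid = np.linspace(*ll.domain, 2001)
    hl = syn.from_table(
        grid,
        ll.energy(grid)
        + DUAL["correction_kt"] * np.sin(DUAL["wavenumber"] * grid),
    )
    centers = umbrella_centers()
    data = syn.gen_dual_level(
        ll, hl, centers, UMBRELLA["spring_k"], UMBRELLA["beta"],
        UMBRELLA["n_per_window"], seed=DUAL["seed"],
        step_size=UMBRELLA["step_size"], stride=UMBRELLA["stride"],
    )
    states = [
        mk.ThermoState(mode="full", beta=UMBRELLA["beta"],
                       energy_column="U_LL",
                       spring_k=[UMBRELLA["spring_k"]], z_ref=[c])
        for c in centers
    ]
    sets = [
        mk.SampleSet(origin_state=i, cv=t,
                     energies={"U_LL": ull, "U_HL": uhl})
        for i, (t, ull, uhl) in enumerate(
            zip(data.trajectories, data.u_ll, data.u_hl)
        )
    ]
    matrix = mk.build_reduced_matrix(states, sets)
    result = mk.solve_mbar(matrix)
    return {
        "data": data,
        "matrix": matrix,
        "result": result,
        "cv": np.concatenate(data.trajectories),
        "u_hl_pooled": np.concatenate(data.u_hl),
        "u_ll_pooled": np.concatenate(data.u_ll),
    }


def histogram_pmf_with_se(traj, edges, n_blocks=10):
    """PMF from a plain histogram plus per-bin block-averaged SE.

    The block SE (rather than multinomial) is used because well-occupancy in
    a double-well trajectory decorrelates slowly.
    """
    h, _ = np.histogram(traj, edges)
    pmf = np.where(h > 0, -np.log(np.where(h > 0, h, 1) / h.sum()), np.nan)
    vals = []
    for block in np.array_split(np.asarray(traj), n_blocks):
        hb, _ = np.histogram(block, edges)
        v = np.where(hb > 0, -np.log(np.where(hb > 0, hb, 1) / hb.sum()), np.nan)
        vals.append(v - np.nanmean(v))
    se = np.nanstd(np.vstack(vals), axis=0, ddof=1) / np.sqrt(n_blocks)
    return pmf, se, h
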
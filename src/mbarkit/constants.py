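"""Physical constants and unit helpers.

Energies are carried in kcal/mol and temperatures in kelvin everywhere in the
package; reduction to dimensionless units happens exactly once, when the
reduced-potential matrix is built.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041


def beta_from_temperature(temperature_k: float) -> float:
    """Inverse temperature 1/(kB*T) in 1/(kcal/mol) for T in kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1.0 / (KB_KCAL_MOL_K * temperature_k)


def temperature_from_beta(beta: float) -> float:
    """Temperature in kelvin for an inverse energy beta in 1/(kcal/mol)."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return 1.0 / (KB_KCAL_MOL_K * beta)
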
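"""Dynamic epistasis analysis of transcriptional-bursting parameters.

For each bursting parameter, the fractional change f of a perturbation is
the ratio of the bootstrap mean in the perturbed population to that in its
reference population.  The expected effect of a double perturbation under
independence is the product of the single-perturbation fractional changes,
f_exp = f_A * f_B, exactly as multiplicative (growth-based) genetic
interactions are scored.  An observed double effect larger than expected
indicates (partial) redundancy between the perturbed factors (synergy); a
smaller effect indicates same-pathway or opposing function (buffering).

The paper-style visual comparison against the +/- s.d. band is
operationalized as a z-score on the observed-minus-expected difference with
a configurable cutoff (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burst_metrics import PopulationSummary
from .stats_boot import propagate_ratio

__all__ = [
    "EffectEstimate",
    "EpistasisCall",
    "fractional_change",
    "expected_double",
    "classify_interaction",
    "load_reference_rules",
    "relative_reference_resolve",
]

ACTIVE_FRACTION = "active_fraction"


@dataclass
class EffectEstimate:
    parameter: str
    f: float
    sd: float
    reference: str
    perturbation: str

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class EpistasisCall:
    observed: EffectEstimate
    expected: EffectEstimate
    z: float
    label: str  # 'synergistic' | 'as-expected' | 'buffered'


def _active_fraction_with_error(summary: PopulationSummary):
    """Active fraction with sqrt(n)-count error propagation.

    With na +- sqrt(na) and ni +- sqrt(ni), f = na/(na+ni) carries
    sd_f = sqrt(ni^2 na + na^2 ni) / n^2.
    """
    na, ni = summary.n_active, summary.n_inactive
    n = na + ni
    if n == 0:
        raise ValueError("empty population")
    frac = na / n
    sd = np.sqrt(ni**2 * na + na**2 * ni) / n**2
    return frac, float(sd)


def fractional_change(
    perturbed: PopulationSummary,
    reference: PopulationSummary,
    parameter: str,
) -> EffectEstimate:
    """Fractional change of one parameter: perturbed over reference.

    Bursting parameters use bootstrap means and bootstrap s.d.s; the active
    fraction uses counts with sqrt(n) errors.
    """
    if parameter == ACTIVE_FRACTION:
        xp, sp = _active_fraction_with_error(perturbed)
        xr, sr = _active_fraction_with_error(reference)
    else:
        for s in (perturbed, reference):
            if parameter not in s.params:
                raise KeyError(f"parameter {parameter!r} missing from summary {s.condition!r}")
        xp, sp = perturbed.params[parameter].boot_mean, perturbed.params[parameter].boot_sd
        xr, sr = reference.params[parameter].boot_mean, reference.params[parameter].boot_sd
    if xr == 0:
        raise ZeroDivisionError("reference mean is zero")
    f, sd = propagate_ratio(xp, sp, xr, sr)
    return EffectEstimate(
        parameter=parameter,
        f=f,
        sd=sd,
        reference=reference.condition,
        perturbation=perturbed.condition,
    )


def expected_double(effect_a: EffectEstimate, effect_b: EffectEstimate) -> EffectEstimate:
    """Multiplicative expectation for a double perturbation of independent
    processes: f_exp = f_A f_B with product-rule error propagation."""
    if effect_a.parameter != effect_b.parameter:
        raise ValueError("effects describe different parameters")
    if effect_a.reference != effect_b.reference:
        raise ValueError("effects use different reference conditions")
    f = effect_a.f * effect_b.f
    rel = []
    for e in (effect_a, effect_b):
        rel.append(e.sd / e.f if e.f != 0 else 0.0)
    sd = abs(f) * float(np.hypot(*rel))
    return EffectEstimate(
        parameter=effect_a.parameter,
        f=f,
        sd=sd,
        reference=effect_a.reference,
        perturbation=f"{effect_a.perturbation}&{effect_b.perturbation}",
    )


def classify_interaction(
    observed: EffectEstimate,
    expected: EffectEstimate,
    z_cut: float = 2.0,
) -> EpistasisCall:
    """Score observed vs expected double-perturbation effects.

    z = (f_obs - f_exp) / sqrt(sd_obs^2 + sd_exp^2); beyond +z_cut the
    perturbations are called synergistic (redundant factors), beyond -z_cut
    buffered (same pathway / opposing functions), otherwise as-expected
    (independent processes).
    """
    if observed.parameter != expected.parameter:
        raise ValueError("observed and expected describe different parameters")
    denom = np.hypot(observed.sd, expected.sd)
    if denom == 0:
        z = 0.0 if observed.f == expected.f else np.sign(observed.f - expected.f) * np.inf
    else:
        z = (observed.f - expected.f) / denom
    if z > z_cut:
        label = "synergistic"
    elif z < -z_cut:
        label = "buffered"
    else:
        label = "as-expected"
    return EpistasisCall(observed=observed, expected=expected, z=float(z), label=label)


def load_reference_rules(path) -> dict:
    """Read a perturbation -> reference override mapping from a YAML file
    (a flat mapping of condition labels)."""
    import yaml

    with open(path) as fh:
        rules = yaml.safe_load(fh) or {}
    if not isinstance(rules, dict):
        raise ValueError("rules file must contain a mapping of condition -> reference")
    return rules


def relative_reference_resolve(condition_table, rules: dict | None = None) -> dict:
    """Map each perturbed condition to its reference condition.

    ``condition_table`` is a DataFrame with columns ``condition``, ``strain``
    and ``treatment``; the default baseline of a perturbed condition is the
    unperturbed (DMSO) condition of the same strain.  ``rules`` overrides the
    mapping per condition, e.g. scoring a histone-gene deletion in
    RSC-depleted cells relative to the RSC-depleted baseline.

    Raises ``KeyError`` listing candidate baselines when no reference exists.
    """
    rules = dict(rules or {})
    mapping: dict = {}
    df = condition_table
    required = {"condition", "strain", "treatment"}
    if not required.issubset(df.columns):
        raise ValueError(f"condition table needs columns {sorted(required)}")
    baselines = df[df["treatment"].str.upper() == "DMSO"]
    for _, row in df.iterrows():
        cond = row["condition"]
        if cond in rules:
            ref = rules[cond]
            if ref not in set(df["condition"]):
                raise KeyError(
                    f"rule for {cond!r} names unknown reference {ref!r}; "
                    f"candidates: {sorted(df['condition'])}"
                )
            mapping[cond] = ref
            continue
        if row["treatment"].upper() == "DMSO":
            continue  # baseline itself
        match = baselines[baselines["strain"] == row["strain"]]
        if len(match) == 0:
            raise KeyError(
                f"no DMSO baseline for condition {cond!r} (strain {row['strain']!r}); "
                f"candidates: {sorted(baselines['condition'])}"
            )
        mapping[cond] = match["condition"].iloc[0]
    return mapping
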
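"""The failure-mode filter cascade and its cohort-level evaluation.

Three rules target the three observed failure mechanisms:

- ``synthesis_risk`` — repetitive, GC-extreme DNA that fails vendor
  synthesis: fires when entropy_dna < 1.85 bits AND gc >= 0.65 (one failure
  mode, so the conditions are conjoined);
- ``recovery_filter`` — designs unlikely to survive the proliferation
  screen: fires when (gc >= 0.60 AND entropy_dna < 1.9) OR
  aa_dinucleotide_repeats >= 45 OR ee_repeats >= 8 OR ke_helix_ratio >= 0.30
  (independent mechanisms, so disjuncts);
- ``cysteine_filter`` — any cysteine (cys_count >= 1), targeting
  disulfide-driven depletion; off by default since it also discards some
  recovered designs.

All thresholds are configurable and the boolean structure is explicit in
the serialized spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds of the filter cascade (all inclusive, ">=" / "<")."""

    synthesis_entropy_max: float = 1.85
    synthesis_gc_min: float = 0.65
    recovery_gc_min: float = 0.60
    recovery_entropy_max: float = 1.9
    aa_repeats_min: int = 45
    ee_repeats_min: int = 8
    ke_helix_min: float = 0.30
    cys_min: int = 1
    glutamate_repeat_semantics: str = "overlapping_ee"  # or "run_residues"
    use_synthesis: bool = True
    use_recovery: bool = True
    use_cysteine: bool = False

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, (int, float)) and not np.isfinite(value):
                raise ValueError(f"non-finite threshold {name}")
        if self.glutamate_repeat_semantics not in ("overlapping_ee", "run_residues"):
            raise ValueError(
                f"unknown glutamate_repeat_semantics {self.glutamate_repeat_semantics!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterSpec":
        try:
            return cls(**dict(d))
        except TypeError as exc:
            raise ValueError(f"malformed filter spec: {exc}") from exc


def apply_filter(features: pd.DataFrame, spec: FilterSpec | None = None) -> pd.DataFrame:
    """Evaluate the cascade on a feature table.

    Returns a DataFrame indexed like ``features`` (by design_id when that
    column is present) with boolean columns ``synthesis_risk``,
    ``recovery_filter``, ``cysteine_filter``, and ``removed`` (the OR of the
    active rules). A missing ke_helix_ratio column (no structures supplied)
    skips that disjunct with a warning.
    """
    spec = spec or FilterSpec()
    df = features.set_index("design_id") if "design_id" in features.columns else features

    required = {"entropy_dna", "gc_content", "aa_dinucleotide_repeats"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")

    synthesis = (df["entropy_dna"] < spec.synthesis_entropy_max) & (
        df["gc_content"] >= spec.synthesis_gc_min
    )

    ee_col = (
        "ee_repeats" if spec.glutamate_repeat_semantics == "overlapping_ee" else "e_run_residues"
    )
    recovery = (df["gc_content"] >= spec.recovery_gc_min) & (
        df["entropy_dna"] < spec.recovery_entropy_max
    )
    recovery |= df["aa_dinucleotide_repeats"] >= spec.aa_repeats_min
    if ee_col in df.columns:
        recovery |= df[ee_col] >= spec.ee_repeats_min
    else:
        warnings.warn(f"feature {ee_col!r} missing; glutamate-repeat rule skipped")
    if "ke_helix_ratio" in df.columns and df["ke_helix_ratio"].notna().any():
        recovery |= df["ke_helix_ratio"].fillna(-np.inf) >= spec.ke_helix_min
    else:
        warnings.warn("ke_helix_ratio missing; K+E-helix rule skipped")

    cysteine = (
        df["cys_count"] >= spec.cys_min
        if "cys_count" in df.columns
        else pd.Series(False, index=df.index)
    )

    removed = pd.Series(False, index=df.index)
    if spec.use_synthesis:
        removed |= synthesis
    if spec.use_recovery:
        removed |= recovery
    if spec.use_cysteine:
        removed |= cysteine

    return pd.DataFrame(
        {
            "synthesis_risk": synthesis,
            "recovery_filter": recovery,
            "cysteine_filter": cysteine,
            "removed": removed,
        }
    )


def evaluate_filter(
    report: pd.DataFrame,
    outcomes: pd.DataFrame,
    hit_denominator: str = "retained",
) -> dict[str, float]:
    """Cohort-level effect of a filter.

    ``outcomes`` must carry boolean ``recovered`` and a ``category`` column;
    designs present in the report but absent from outcomes (e.g. synthesis
    failures) are excluded from the rate denominators.

    ``hit_denominator`` selects the convention for the hit rate: over all
    retained designs ("retained", default) or over retained AND recovered
    designs ("recovered").
    """
    if hit_denominator not in ("retained", "recovered"):
        raise ValueError("hit_denominator must be 'retained' or 'recovered'")
    out = outcomes.set_index("design_id") if "design_id" in outcomes.columns else outcomes
    common = report.index.intersection(out.index)
    removed = report.loc[common, "removed"]
    rec = out.loc[common, "recovered"].astype(bool)
    hit = out.loc[common, "category"] == "enriched"

    def rates(mask: pd.Series) -> tuple[float, float]:
        n = int(mask.sum())
        if n == 0:
            return np.nan, np.nan
        pct_rec = rec[mask].mean() * 100
        if hit_denominator == "recovered":
            denom = mask & rec
            pct_hit = hit[denom].mean() * 100 if denom.any() else np.nan
        else:
            pct_hit = hit[mask].mean() * 100
        return pct_rec, pct_hit

    all_mask = pd.Series(True, index=common)
    base_rec, base_hit = rates(all_mask)
    kept_rec, kept_hit = rates(~removed)
    return {
        "n_total": int(len(common)),
        "n_removed": int(removed.sum()),
        "n_retained": int((~removed).sum()),
        "pct_recovered_before": base_rec,
        "pct_recovered_after": kept_rec,
        "pct_hits_before": base_hit,
        "pct_hits_after": kept_hit,
    }


def sweep_thresholds(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    grid: Iterable[Mapping],
    base_spec: FilterSpec | None = None,
    hit_denominator: str = "retained",
) -> pd.DataFrame:
    """Evaluate the cascade over a grid of threshold overrides.

    Each grid point is a mapping of FilterSpec field overrides; rows come
    back in grid order with the overrides and the evaluation metrics.
    """
    base = base_spec or FilterSpec()
    rows = []
    for point in grid:
        spec = replace(base, **dict(point))
        report = apply_filter(features, spec)
        metrics = evaluate_filter(report, outcomes, hit_denominator=hit_denominator)
        rows.append({**dict(point), **metrics})
    cols = None
    if rows:
        cols = list(rows[0].keys())
    return pd.DataFrame(rows, columns=cols)
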
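"""Profile standardization, orientation, sorting and pattern annotation.

Selected genes are z-scored (per gene), oriented so every profile rises —
a gene is "ascending" when its raw mean in the terminal stage exceeds its
raw mean in the initial stage, "descending" otherwise — and their values are
sorted by intensity before SOM clustering.  Sorting by intensity rather than
by fixed sample position makes the profiles robust to noisy samples: a
mildly out-of-place sample slides to where its signal belongs while most
samples keep their stage order.

Each resulting pattern is annotated with its half-change (delta/2) point:
the interpolated stage coordinate at which the pattern's mean per-stage
profile has completed half of its total change delta.  Patterns whose
half-change point falls in the first half of the stage axis change "early"
in the disease; the rest change "late".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, StageDesign
from .som import SOMPatternModel

__all__ = [
    "OrientedProfile",
    "PatternSummary",
    "standardize_and_orient",
    "compute_half_change",
    "summarize_patterns",
]


@dataclass
class OrientedProfile:
    gene_id: str
    orientation: str  # "ascending" | "descending"
    sorted_values: np.ndarray  # standardized values sorted by orientation
    sorted_sample_stages: np.ndarray  # stage codes carried along with the sort
    stage_means: np.ndarray  # per-stage mean z-score, sign-flipped if descending


@dataclass
class PatternSummary:
    unit: int
    gene_ids: list[str]
    main: bool
    mean_stage_profile: np.ndarray
    delta: float
    half_change_position: float
    trend_class: str  # "early" | "late"
    flat: bool
    n_up: int
    n_down: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def standardize_and_orient(
    expr: ExpressionMatrix,
    design: StageDesign,
    gene_ids: list[str],
    ddof: int = 0,
) -> list[OrientedProfile]:
    """Z-score, orient and intensity-sort the selected genes.

    Standardization subtracts the gene's mean and divides by its standard
    deviation (population n-denominator by default; ``ddof=1`` for the
    sample convention).  Stage means are computed on the unsorted z-scores
    and multiplied by -1 for descending genes so all profiles rise on one
    comparable scale.
    """
    if list(expr.sample_ids) != list(design.sample_ids):
        raise ValueError("expression matrix and stage design are not aligned")
    codes = design.codes_for(expr.sample_ids)
    k_stages = design.n_stages
    first_mask = codes == 1
    last_mask = codes == k_stages
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    profiles: list[OrientedProfile] = []
    for gid in gene_ids:
        try:
            row = expr.values[gene_index[gid]]
        except KeyError:
            raise ValueError(f"gene {gid!r} not present in expression matrix") from None
        sd = row.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"gene {gid!r} has zero variance; cannot standardize")
        z = (row - row.mean()) / sd
        ascending = row[last_mask].mean() > row[first_mask].mean()
        order = np.argsort(z, kind="stable")
        if not ascending:
            order = order[::-1]
        sign = 1.0 if ascending else -1.0
        stage_means = np.array(
            [z[codes == k].mean() for k in range(1, k_stages + 1)]
        ) * sign
        profiles.append(
            OrientedProfile(
                gene_id=gid,
                orientation="ascending" if ascending else "descending",
                sorted_values=z[order],
                sorted_sample_stages=codes[order],
                stage_means=stage_means,
            )
        )
    return profiles


def compute_half_change(stage_profile: np.ndarray) -> tuple[float, float, str]:
    """Half-change annotation of a (rising) per-stage profile.

    Returns ``(delta, position, trend_class)`` where delta = max - min,
    position is the smallest stage coordinate t in [1, K] at which the
    piecewise-linear interpolation of the profile first reaches
    min + delta/2, and trend_class is "early" if position <= (K+1)/2 else
    "late".  A flat profile (delta = 0) yields position 1 and class "early"
    by convention.
    """
    v = np.asarray(stage_profile, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("stage profile must be 1-D with K >= 2")
    k = v.size
    delta = float(v.max() - v.min())
    if delta == 0:
        return 0.0, 1.0, "early"
    threshold = v.min() + delta / 2.0
    idx = int(np.argmax(v >= threshold))  # first index reaching the threshold
    if idx == 0:
        position = 1.0
    else:
        v0, v1 = v[idx - 1], v[idx]
        position = idx + (threshold - v0) / (v1 - v0)  # 1-based: idx = prior point
    trend_class = "early" if position <= (k + 1) / 2.0 else "late"
    return delta, float(position), trend_class


def summarize_patterns(
    model: SOMPatternModel,
    profiles: list[OrientedProfile],
    design: StageDesign,
    min_fraction: float = 0.05,
) -> list[PatternSummary]:
    """One summary per non-empty SOM unit, ordered by unit index.

    A unit holding at least ``min_fraction`` of the clustered genes is
    flagged as a "main" pattern.  The mean stage profile averages the
    members' (sign-oriented) per-stage z-score means; delta/2 annotation is
    computed on that mean profile.
    """
    by_gene = {p.gene_id: p for p in profiles}
    missing = [g for g in model.assignments if g not in by_gene]
    if missing:
        raise ValueError(f"profiles missing for assigned genes: {missing[:5]}")
    n_total = len(model.assignments)
    summaries: list[PatternSummary] = []
    for unit in range(model.n_units):
        member_ids = [g for g, u in model.assignments.items() if u == unit]
        if not member_ids:
            continue
        members = [by_gene[g] for g in member_ids]
        mean_profile = np.mean([m.stage_means for m in members], axis=0)
        delta, position, trend_class = compute_half_change(mean_profile)
        summaries.append(
            PatternSummary(
                unit=unit,
                gene_ids=member_ids,
                main=len(member_ids) >= min_fraction * n_total,
                mean_stage_profile=mean_profile,
                delta=delta,
                half_change_position=position,
                trend_class=trend_class,
                flat=delta == 0.0,
                n_up=sum(m.orientation == "ascending" for m in members),
                n_down=sum(m.orientation == "descending" for m in members),
            )
        )
    return summaries


def membership_table(
    model: SOMPatternModel,
    profiles: list[OrientedProfile],
    gamma_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene pattern membership: gene_id, unit, orientation (+ gamma)."""
    rows = pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "unit": [model.assignments[p.gene_id] for p in profiles],
            "orientation": [p.orientation for p in profiles],
        }
    )
    if gamma_table is not None:
        rows = rows.merge(gamma_table[["gene_id", "gamma"]], on="gene_id", how="left")
    return rows


def summary_table(summaries: list[PatternSummary], design: StageDesign) -> pd.DataFrame:
    """Tabular pattern summaries with one mean-profile column per stage."""
    records = []
    for s in summaries:
        rec = {
            "unit": s.unit,
            "n_genes": s.n_genes,
            "main": s.main,
            "delta": s.delta,
            "half_change_position": s.half_change_position,
            "trend_class": s.trend_class,
            "flat": s.flat,
            "n_up": s.n_up,
            "n_down": s.n_down,
        }
        for level, value in zip(design.stage_levels, s.mean_stage_profile):
            rec[f"mean_{level}"] = value
        records.append(rec)
    return pd.DataFrame.from_records(records)
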
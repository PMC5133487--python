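"""Expression matrices and ordinal stage designs, with delimited-text I/O.

Expression data are genes x samples tables (TSV or CSV; header row of sample
ids, first column of feature ids).  Stage designs map each sample to one of an
ordered list of disease stages, from the initial/control stage to the most
acute one; the order is always supplied by the user because it encodes
clinical progression that no lexical sort can recover.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_SCALES = ("linear_counts", "log_signal")


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with unique string identifiers.

    ``values`` holds either raw counts (``value_scale='linear_counts'``) or
    log-scale signal such as log2 intensity or log2(RPKM+1)
    (``value_scale='log_signal'``).  All values must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_scale: str = "log_signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValueError(f"duplicate {name} ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r} ({len(bad)} total)"
            )
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"value_scale must be one of {VALUE_SCALES}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, cols], self.value_scale
        )

    def log2_plus1(self) -> "ExpressionMatrix":
        """Return a copy transformed to log2(x+1), marked as log_signal."""
        if np.any(self.values < -1):
            raise ValueError("log2(x+1) undefined for values below -1")
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            np.log2(self.values + 1.0),
            "log_signal",
        )


@dataclass
class StageDesign:
    """Ordinal stage assignment: stage_levels[0] is the initial/control stage,
    stage_levels[-1] the terminal/acute stage.  Ordinal codes run 1..K."""

    stage_levels: list[str]
    sample_to_stage: dict[str, str]
    ordinal_codes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stage_levels) < 2:
            raise ValueError("need at least 2 stage levels")
        dup = _duplicates(self.stage_levels)
        if dup:
            raise ValueError(f"duplicate stage levels: {sorted(dup)}")
        if not self.ordinal_codes:
            self.ordinal_codes = {s: k + 1 for k, s in enumerate(self.stage_levels)}
        codes = [self.ordinal_codes[s] for s in self.stage_levels]
        if any(b <= a for a, b in zip(codes, codes[1:])):
            raise ValueError("ordinal codes must be strictly increasing along stage_levels")
        level_set = set(self.stage_levels)
        for sample, stage in self.sample_to_stage.items():
            if stage not in level_set:
                raise ValueError(f"sample {sample!r} maps to unknown stage {stage!r}")
        counts = self.stage_counts()
        empty = [s for s in self.stage_levels if counts[s] == 0]
        if empty:
            raise ValueError(f"empty stage {empty[0]}")
        small = [s for s in self.stage_levels if counts[s] < 3]
        if small:
            warnings.warn(
                f"stages with fewer than 3 samples: {small}", UserWarning, stacklevel=2
            )

    @property
    def n_stages(self) -> int:
        return len(self.stage_levels)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_to_stage)

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in self.stage_levels}
        for stage in self.sample_to_stage.values():
            counts[stage] += 1
        return counts

    def codes_for(self, sample_ids: list[str]) -> np.ndarray:
        """Ordinal codes (1..K) for the given samples, in the given order."""
        return np.array(
            [self.ordinal_codes[self.sample_to_stage[s]] for s in sample_ids], dtype=float
        )

    def subset(self, sample_ids: list[str]) -> "StageDesign":
        mapping = {s: self.sample_to_stage[s] for s in sample_ids}
        kept = {stage for stage in mapping.values()}
        levels = [s for s in self.stage_levels if s in kept]
        codes = {s: k + 1 for k, s in enumerate(levels)}
        return StageDesign(levels, mapping, codes)


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _detect_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValueError(f"could not detect delimiter (tab or comma) in {path}")


def read_expression(
    path: str,
    transform: str = "none",
    delimiter: str | None = None,
    value_scale: str = "linear_counts",
) -> ExpressionMatrix:
    """Load a genes x samples delimited text matrix.

    Parameters
    ----------
    transform
        ``"none"`` keeps values as loaded; ``"log2_plus1"`` applies
        log2(x+1) elementwise and marks the result as log-scale.
    value_scale
        Scale of the values *as stored in the file* (ignored when
        ``transform="log2_plus1"``, which always yields ``log_signal``).
    """
    if transform not in ("none", "log2_plus1"):
        raise ValueError(f"unknown transform {transform!r}")
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup = _duplicates(gene_ids)
    if dup:
        raise ValueError(f"duplicate gene ids in {path}: {sorted(dup)}")
    dup = _duplicates(sample_ids)
    if dup:
        raise ValueError(f"duplicate sample ids in {path}: {sorted(dup)}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for a useful message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at gene {gene_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}"
                    ) from None
        raise
    if np.any(np.isnan(values)):
        bad = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at gene {gene_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
        )
    em = ExpressionMatrix(gene_ids, sample_ids, values, value_scale)
    if transform == "log2_plus1":
        em = em.log2_plus1()
    return em


def write_expression(em: ExpressionMatrix, path: str, sig_digits: int = 6) -> None:
    """Write a matrix as TSV, reals at ``sig_digits`` significant digits."""
    em.to_frame().to_csv(path, sep="\t", float_format=f"%.{sig_digits}g")


def read_stage_design(path: str, stage_order: list[str], delimiter: str | None = None) -> StageDesign:
    """Load a two-column (sample_id, stage) annotation restricted to
    ``stage_order``; ordinal codes follow the supplied order."""
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"stage annotation {path} needs 2 columns, found {df.shape[1]}")
    if list(df.iloc[0, :2]) == ["sample_id", "stage"]:  # tolerate our own header
        df = df.iloc[1:]
    order_set = set(stage_order)
    mapping: dict[str, str] = {}
    for sample, stage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sample, stage = str(sample).strip(), str(stage).strip()
        if stage not in order_set:
            raise ValueError(f"sample {sample!r} has unknown stage label {stage!r}")
        if sample in mapping:
            raise ValueError(f"duplicate sample id {sample!r} in {path}")
        mapping[sample] = stage
    return StageDesign(list(stage_order), mapping)


def write_stage_design(design: StageDesign, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstage\n")
        for sample, stage in design.sample_to_stage.items():
            fh.write(f"{sample}\t{stage}\n")


def merge_stages(
    design: StageDesign, merge_map: dict[str, str], new_order: list[str]
) -> StageDesign:
    """Collapse stage levels (e.g. disease subtypes into risk groups).

    ``merge_map`` must cover every original level; ``new_order`` gives the
    progression order of the merged labels.
    """
    missing = [s for s in design.stage_levels if s not in merge_map]
    if missing:
        raise ValueError(f"merge_map missing original stage levels: {missing}")
    targets = {merge_map[s] for s in design.stage_levels}
    absent = targets - set(new_order)
    if absent:
        raise ValueError(f"new_order missing merged labels: {sorted(absent)}")
    mapping = {smp: merge_map[stage] for smp, stage in design.sample_to_stage.items()}
    return StageDesign(list(new_order), mapping)


def align(
    expr: ExpressionMatrix, design: StageDesign
) -> tuple[ExpressionMatrix, StageDesign]:
    """Restrict both objects to shared samples, columns sorted by stage then
    by design input order.  Dropped samples are logged."""
    expr_set = set(expr.sample_ids)
    shared = [s for s in design.sample_ids if s in expr_set]
    if not shared:
        raise ValueError("no shared samples between expression matrix and stage design")
    dropped = sorted((expr_set | set(design.sample_ids)) - set(shared))
    if dropped:
        logger.info("align: dropped samples without both expression and stage: %s", dropped)
    shared.sort(key=lambda s: design.ordinal_codes[design.sample_to_stage[s]])  # stable
    return expr.subset_samples(shared), design.subset(shared)
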
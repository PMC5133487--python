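"""End-to-end run: align -> (merge) -> gamma screen -> profiles -> SOM -> patterns.

One global seed fans out to independent per-phase streams (permutations, SOM
initialization) so a phase can be re-run in isolation yet the whole pipeline
stays reproducible: identical inputs and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gamma import GammaParams, screen_genes, write_gamma_table
from .io import (
    ExpressionMatrix,
    StageDesign,
    align,
    merge_stages,
    read_expression,
    read_stage_design,
)
from .patterns import (
    membership_table,
    standardize_and_orient,
    summarize_patterns,
    summary_table,
)
from .som import SOMTrainingParams, train_som

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "gamma.tsv",
    "membership.tsv",
    "patterns.tsv",
    "codebook.tsv",
    "manifest.json",
)


@dataclass
class RunConfig:
    expression_path: str
    stages_path: str
    stage_order: list[str]
    out_dir: str
    merge_map: dict[str, str] | None = None
    merged_order: list[str] | None = None
    transform: str = "auto"  # auto: log2(x+1) when the matrix holds counts
    value_scale: str = "linear_counts"
    gamma: GammaParams = field(default_factory=GammaParams)
    grid_rows: int = 3
    grid_cols: int = 3
    som: SOMTrainingParams = field(default_factory=SOMTrainingParams)
    min_fraction: float = 0.05
    seed: int = 0


def _phase_seeds(seed: int, n: int = 4) -> list[int]:
    """Fan a global seed out to independent 31-bit per-phase seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all output tables.

    Returns the run manifest (also written as ``manifest.json``).  On any
    phase error, partial outputs are removed and the error is re-raised with
    a phase tag.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phase = "setup"
    timings: dict[str, float] = {}
    gamma_seed, som_seed = _phase_seeds(config.seed, 2)
    try:
        phase = "load"
        t0 = time.perf_counter()
        transform = config.transform
        expr = read_expression(
            config.expression_path, transform="none", value_scale=config.value_scale
        )
        if transform == "auto":
            transform = "log2_plus1" if expr.value_scale == "linear_counts" else "none"
        if transform == "log2_plus1":
            expr = expr.log2_plus1()
        design = read_stage_design(config.stages_path, config.stage_order)
        timings[phase] = time.perf_counter() - t0

        if config.merge_map:
            phase = "merge"
            t0 = time.perf_counter()
            design = merge_stages(
                design, config.merge_map, config.merged_order or config.stage_order
            )
            timings[phase] = time.perf_counter() - t0

        phase = "align"
        t0 = time.perf_counter()
        expr, design = align(expr, design)
        timings[phase] = time.perf_counter() - t0

        phase = "gamma_screen"
        t0 = time.perf_counter()
        gparams = GammaParams(**{**asdict(config.gamma), "seed": gamma_seed})
        gamma_table = screen_genes(expr, design, gparams)
        write_gamma_table(gamma_table, str(out / "gamma.tsv"))
        timings[phase] = time.perf_counter() - t0
        selected = gamma_table.loc[gamma_table["selected"], "gene_id"].tolist()
        logger.info(
            "gamma screen: %d/%d genes selected", len(selected), len(gamma_table)
        )

        phase = "patterns"
        t0 = time.perf_counter()
        manifest: dict = {
            "package_version": __version__,
            "config": _serializable(config),
            "inputs": {
                "expression": _checksum(config.expression_path),
                "stages": _checksum(config.stages_path),
            },
            "stage_counts": design.stage_counts(),
            "n_genes_tested": int(gamma_table["p_perm"].notna().sum()),
            "n_genes_undefined": int(gamma_table["p_perm"].isna().sum()),
            "n_genes_selected": len(selected),
        }
        if selected:
            profiles = standardize_and_orient(expr, design, selected)
            som_params = SOMTrainingParams(
                **{**asdict(config.som), "seed": som_seed}
            )
            model = train_som(
                np.array([p.sorted_values for p in profiles]),
                [p.gene_id for p in profiles],
                grid=(config.grid_rows, config.grid_cols),
                params=som_params,
            )
            summaries = summarize_patterns(model, profiles, design, config.min_fraction)
            membership_table(model, profiles, gamma_table).to_csv(
                out / "membership.tsv", sep="\t", index=False, float_format="%.6g"
            )
            summary_table(summaries, design).to_csv(
                out / "patterns.tsv", sep="\t", index=False, float_format="%.6g"
            )
            _write_codebook(model, out / "codebook.tsv")
            manifest["unit_sizes"] = model.unit_sizes.tolist()
            manifest["n_main_patterns"] = sum(s.main for s in summaries)
        else:
            for name in ("membership.tsv", "patterns.tsv", "codebook.tsv"):
                (out / name).write_text("")
            manifest["unit_sizes"] = []
            manifest["n_main_patterns"] = 0
        timings[phase] = time.perf_counter() - t0

        manifest["timings_sec"] = {k: round(v, 3) for k, v in timings.items()}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        for name in OUTPUT_FILES:
            path = out / name
            if path.exists():
                path.unlink()
        raise RuntimeError(f"pipeline failed in phase {phase!r}: {exc}") from exc


def _write_codebook(model, path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"c{i + 1}" for i in range(model.codebook.shape[1]))
        fh.write(f"unit\trow\tcol\t{cols}\n")
        for u in range(model.n_units):
            vec = "\t".join(f"{v:.6g}" for v in model.codebook[u])
            fh.write(f"{u}\t{u // model.grid_cols}\t{u % model.grid_cols}\t{vec}\n")


def _serializable(config: RunConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))
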
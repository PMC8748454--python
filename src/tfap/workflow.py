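"""End-to-end screen orchestration.

The screen composes the pipeline stages in order: per-drug differential
expression against pooled same-cell-line controls, TF-target enrichment of
the up- and down-lists separately across all libraries, MeanRank
integration with the empirical significance threshold, signed activation
states (both-lists TFs excluded), the drugs x TFs activation matrix,
optional reduction to a TF panel, and the pro-differentiation ranking.

:func:`screen` is the in-memory composition used programmatically and in
tests; :func:`run_screen` is the file-based front door that reads a
:class:`RunConfig`, writes every intermediate artifact and a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diffexpr import (
    GeneLists,
    InestimableContrastError,
    derive_gene_lists,
    moderated_t_contrast,
    write_gene_lists,
)
from .enrichment import call_activation_states, significant_tfs
from .expression import ExpressionMatrix, read_expression_table
from .libraries import LibraryCollection, load_collection
from .scoring import (
    ActivationMatrix,
    TFPanel,
    build_activation_matrix,
    filter_to_panel,
    rank_drugs,
    write_activation_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    expression: str
    metadata: str
    libraries: str  # YAML manifest: library name -> GMT path
    panel: str | None = None
    cell_line: str | None = None
    alpha_de: float = 0.05
    lfc_min: float = 0.0
    alpha_enrich: float = 0.05
    min_list_size: int = 1
    drop_inert: bool = True
    inclusive_boundary: bool = True
    missing_tf_rule: str = "penalize"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_enrich"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.min_list_size < 1:
            raise ValueError("min_list_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ScreenResult:
    """Outputs of one screen on one cell line."""

    cell_line: str
    gene_lists: dict  # drug -> GeneLists (analysable drugs only)
    skipped: dict  # drug -> reason string
    states: dict  # drug -> {tf -> state}
    matrix: ActivationMatrix
    panel_matrix: ActivationMatrix | None
    missing_panel_tfs: list
    ranking: "object"  # pandas DataFrame
    params: dict


def screen(
    expr: ExpressionMatrix,
    collection: LibraryCollection,
    cell_line: str | None = None,
    panel: TFPanel | None = None,
    alpha_de: float = 0.05,
    lfc_min: float = 0.0,
    alpha_enrich: float = 0.05,
    min_list_size: int = 1,
    drop_inert: bool = True,
    inclusive_boundary: bool = True,
    missing_tf_rule: str = "penalize",
) -> ScreenResult:
    """Run the full screen for one cell line, in memory."""
    if cell_line is None:
        lines = expr.cell_lines
        if len(lines) != 1:
            raise ValueError(
                f"dataset has cell lines {lines}; pass cell_line explicitly"
            )
        cell_line = lines[0]
    tf_union = collection.tf_union
    gene_lists: dict = {}
    skipped: dict = {}
    states: dict = {}
    for drug in expr.drugs(cell_line):
        try:
            contrast = moderated_t_contrast(expr, drug, cell_line)
        except InestimableContrastError as exc:
            skipped[drug] = str(exc)
            continue
        lists = derive_gene_lists(
            contrast, alpha=alpha_de, lfc_min=lfc_min, drug_id=drug
        )
        if not lists.is_analysable(min_list_size):
            skipped[drug] = "no significantly modulated genes"
            continue
        gene_lists[drug] = lists
        sig_up = significant_tfs(
            lists.up,
            collection,
            alpha=alpha_enrich,
            missing=missing_tf_rule,
            inclusive=inclusive_boundary,
        )
        sig_down = significant_tfs(
            lists.down,
            collection,
            alpha=alpha_enrich,
            missing=missing_tf_rule,
            inclusive=inclusive_boundary,
        )
        states[drug] = call_activation_states(sig_up, sig_down, tf_union)
    matrix = build_activation_matrix(states)
    panel_matrix = None
    missing_panel: list = []
    score_matrix = matrix
    if panel is not None and len(matrix.drugs) > 0:
        panel_matrix, missing_panel = filter_to_panel(
            matrix, panel, drop_inert=drop_inert
        )
        score_matrix = panel_matrix
    ranking = rank_drugs(score_matrix)
    return ScreenResult(
        cell_line=cell_line,
        gene_lists=gene_lists,
        skipped=skipped,
        states=states,
        matrix=matrix,
        panel_matrix=panel_matrix,
        missing_panel_tfs=missing_panel,
        ranking=ranking,
        params={
            "alpha_de": alpha_de,
            "lfc_min": lfc_min,
            "alpha_enrich": alpha_enrich,
            "min_list_size": min_list_size,
            "drop_inert": drop_inert,
            "inclusive_boundary": inclusive_boundary,
            "missing_tf_rule": missing_tf_rule,
        },
    )


def screen_all_cell_lines(
    expr: ExpressionMatrix, collection: LibraryCollection, **params
) -> dict:
    """Run :func:`screen` per cell line; returns cell line -> ScreenResult."""
    return {
        cl: screen(expr, collection, cell_line=cl, **params)
        for cl in expr.cell_lines
    }


def run_screen(cfg: RunConfig, out_dir: str | Path) -> ScreenResult:
    """File-based screen: read inputs, run, write every stage's artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = read_expression_table(cfg.expression, cfg.metadata)
    collection = load_collection(cfg.libraries, universe=set(expr.gene_ids))
    panel = TFPanel.from_file(cfg.panel) if cfg.panel else None
    result = screen(
        expr,
        collection,
        cell_line=cfg.cell_line,
        panel=panel,
        alpha_de=cfg.alpha_de,
        lfc_min=cfg.lfc_min,
        alpha_enrich=cfg.alpha_enrich,
        min_list_size=cfg.min_list_size,
        drop_inert=cfg.drop_inert,
        inclusive_boundary=cfg.inclusive_boundary,
        missing_tf_rule=cfg.missing_tf_rule,
    )

    lists_dir = out / "gene_lists"
    lists_dir.mkdir(exist_ok=True)
    for drug, lists in result.gene_lists.items():
        write_gene_lists(lists, lists_dir / f"{drug}.tsv")
    (lists_dir / "thresholds.json").write_text(
        json.dumps(
            {
                "alpha": cfg.alpha_de,
                "lfc_min": cfg.lfc_min,
                "min_list_size": cfg.min_list_size,
                "analysable_drugs": sorted(result.gene_lists),
                "skipped_drugs": result.skipped,
            },
            indent=2,
        )
    )
    write_activation_matrix(result.matrix, out / "activation_matrix.tsv")
    if result.panel_matrix is not None:
        write_activation_matrix(result.panel_matrix, out / "panel_matrix.tsv")
    result.ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
    manifest = {
        "tfap_version": __version__,
        "config": asdict(cfg),
        "cell_line": result.cell_line,
        "n_drugs_total": len(result.gene_lists) + len(result.skipped),
        "n_drugs_analysable": len(result.gene_lists),
        "n_tfs": len(result.matrix.tfs),
        "missing_panel_tfs": result.missing_panel_tfs,
        "params": result.params,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "screen complete: %d/%d drugs analysable, %d TFs",
        len(result.gene_lists),
        manifest["n_drugs_total"],
        manifest["n_tfs"],
    )
    return result
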
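"""Synthetic TF libraries and perturbation expression data with ground truth.

Every pipeline stage is exercised against data whose generating mechanism
is known.  The generator emulates the structure of a public perturbation
compendium: several cell lines with distinct per-gene baseline offsets,
vehicle controls, replicated drug treatments, and drug "programs" that
activate or repress chosen TFs by shifting the log-expression of those
TFs' target genes.

Regulon construction: each TF owns a disjoint pool of candidate target
genes (the gene universe partitioned across TFs) from which every library
draws that TF's target set.  Libraries agree on a configurable core
fraction of each regulon (``overlap_frac``) and fill the rest with
library-specific picks from the same pool, emulating partially concordant
annotation resources.  Disjoint pools keep planted regulons identifiable,
so ground-truth recovery is well defined.

Noise draws are scale-separated from the noise level: standard-normal
deviates depend only on the seed and the data shape, and are multiplied by
``noise_sd`` afterwards.  Varying the noise level or effect size at a fixed
seed therefore reuses identical deviates (common random numbers), which
makes recovery-vs-noise comparisons monotone rather than confounded by
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CONTROL, ExpressionMatrix
from .libraries import LibraryCollection, TFLibrary

_DEFAULT_LIBRARY_NAMES = (
    "coexpr_a",
    "chipseq_a",
    "chipseq_b",
    "enrichr_queries",
    "coexpr_b",
    "literature",
    "remap",
)


@dataclass(frozen=True)
class DrugProgram:
    """Planted effect of one drug: signed TF targets and a shift size."""

    drug_id: str
    tf_effects: dict  # tf_id -> +1 | -1
    effect_size: float

    def __post_init__(self) -> None:
        if not self.tf_effects:
            raise ValueError(f"drug {self.drug_id!r}: empty TF effect map")
        if self.effect_size <= 0:
            raise ValueError(f"drug {self.drug_id!r}: effect_size must be > 0")
        bad = set(self.tf_effects.values()) - {1, -1}
        if bad:
            raise ValueError(f"drug {self.drug_id!r}: effects must be +1/-1")


@dataclass
class SimulationTruth:
    """Everything needed to reproduce and evaluate one simulated dataset."""

    programs: list
    collection: LibraryCollection
    noise_sd: float
    cell_line_offset_sd: float
    seed: int
    cell_lines: list = field(default_factory=list)
    null_drugs: list = field(default_factory=list)

    def planted_states(self) -> dict:
        """drug -> {tf -> planted signed state}, 0 for untouched TFs."""
        union = self.collection.tf_union
        out = {}
        for prog in self.programs:
            states = {tf: 0 for tf in union}
            states.update(prog.tf_effects)
            out[prog.drug_id] = states
        for drug in self.null_drugs:
            out[drug] = {tf: 0 for tf in union}
        return out


def simulate_library_collection(
    n_libraries: int,
    n_tfs: int,
    n_genes: int,
    targets_per_tf: int,
    overlap_frac: float = 0.8,
    seed: int = 0,
    library_names: tuple | None = None,
) -> LibraryCollection:
    """Generate partially concordant TF-target libraries over one universe."""
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in [0, 1]")
    if n_libraries < 1 or n_tfs < 1:
        raise ValueError("need at least one library and one TF")
    pool_size = n_genes // n_tfs
    if targets_per_tf > pool_size:
        raise ValueError(
            f"targets_per_tf={targets_per_tf} exceeds the per-TF gene pool "
            f"({pool_size} = {n_genes} genes / {n_tfs} TFs)"
        )
    if library_names is None:
        library_names = tuple(
            _DEFAULT_LIBRARY_NAMES[i]
            if i < len(_DEFAULT_LIBRARY_NAMES)
            else f"library_{i + 1}"
            for i in range(n_libraries)
        )
    if len(library_names) != n_libraries:
        raise ValueError("library_names length must equal n_libraries")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(n_genes)])
    universe = frozenset(genes)
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    n_core = round(overlap_frac * targets_per_tf)
    per_library_sets: list = [dict() for _ in range(n_libraries)]
    for t, tf in enumerate(tf_ids):
        pool = genes[t * pool_size : (t + 1) * pool_size]
        core = rng.choice(pool, size=n_core, replace=False)
        rest = np.setdiff1d(pool, core)
        for sets in per_library_sets:
            extra = rng.choice(
                rest, size=targets_per_tf - n_core, replace=False
            )
            sets[tf] = frozenset(core) | frozenset(extra)
    libs = tuple(
        TFLibrary(name=library_names[i], sets=per_library_sets[i], universe=universe)
        for i in range(n_libraries)
    )
    return LibraryCollection(libraries=libs)


def random_programs(
    tf_ids: list,
    n_drugs: int,
    tfs_per_drug: int = 2,
    effect_size: float = 2.0,
    activation_prob: float = 0.5,
    seed: int = 0,
) -> list:
    """Draw random drug programs over the given TFs."""
    rng = np.random.default_rng(seed)
    tf_ids = list(tf_ids)
    width = len(str(n_drugs))
    programs = []
    for d in range(n_drugs):
        chosen = rng.choice(tf_ids, size=tfs_per_drug, replace=False)
        effects = {
            tf: 1 if rng.random() < activation_prob else -1 for tf in chosen
        }
        programs.append(
            DrugProgram(
                drug_id=f"D{d + 1:0{width}d}",
                tf_effects=effects,
                effect_size=effect_size,
            )
        )
    return programs


def _target_union(collection: LibraryCollection, tf: str) -> frozenset:
    out: set = set()
    for lib in collection:
        out |= lib.sets.get(tf, frozenset())
    return frozenset(out)


def simulate_perturbation_dataset(
    collection: LibraryCollection,
    programs: list,
    n_cell_lines: int = 3,
    n_replicates: int = 2,
    n_controls: int = 2,
    noise_sd: float = 0.5,
    cell_line_offset_sd: float = 2.0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    n_null_drugs: int = 0,
    gene_noise_df: float | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate controls and drug treatments across cell lines.

    Per cell line: ``n_controls`` vehicle samples plus ``n_replicates``
    treated samples per drug.  Controls are baseline + cell-line offset +
    Gaussian noise; treated samples additionally shift every target gene of
    each programmed TF by ``±effect_size`` (sign per planted effect, shared
    across cell lines).  ``n_null_drugs`` extra drugs carry no program.

    ``gene_noise_df`` switches on gene-specific noise levels: per-gene
    variances are drawn once from a scaled inverse chi-square with that
    many degrees of freedom around ``noise_sd**2`` (small df = strongly
    heteroscedastic genes, as in real expression data); ``None`` keeps a
    common ``noise_sd`` for every gene.
    """
    tf_union = collection.tf_union
    for prog in programs:
        unknown = set(prog.tf_effects) - tf_union
        if unknown:
            raise ValueError(
                f"drug {prog.drug_id!r} references TFs absent from the "
                f"libraries: {sorted(unknown)}"
            )
    genes = sorted(collection.libraries[0].universe)
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    cell_lines = [f"CL{i + 1}" for i in range(n_cell_lines)]
    null_drugs = [f"N{i + 1:03d}" for i in range(n_null_drugs)]
    drug_ids = [p.drug_id for p in programs] + null_drugs

    columns: list = []
    meta_rows: list = []
    for cl in cell_lines:
        for r in range(n_controls):
            columns.append(f"{cl}:CONTROL:{r + 1}")
            meta_rows.append((CONTROL, cl, r + 1))
        for drug in drug_ids:
            for r in range(n_replicates):
                columns.append(f"{cl}:{drug}:{r + 1}")
                meta_rows.append((drug, cl, r + 1))
    n_samples = len(columns)

    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    offsets = rng.normal(0.0, 1.0, (n_cell_lines, n_genes)) * cell_line_offset_sd
    if gene_noise_df is not None:
        gene_sd = np.sqrt(gene_noise_df / rng.chisquare(gene_noise_df, n_genes))
    else:
        gene_sd = np.ones(n_genes)
    z = rng.standard_normal((n_genes, n_samples))

    values = np.empty((n_genes, n_samples))
    values[:] = baseline[:, None] + noise_sd * gene_sd[:, None] * z
    for j, (_, cl, _) in enumerate(meta_rows):
        values[:, j] += offsets[cell_lines.index(cl)]
    for prog in programs:
        cols = [
            j for j, (d, _, _) in enumerate(meta_rows) if d == prog.drug_id
        ]
        for tf, sign in prog.tf_effects.items():
            rows = [gene_index[g] for g in _target_union(collection, tf)]
            values[np.ix_(rows, cols)] += sign * prog.effect_size

    expr = ExpressionMatrix(
        values=pd.DataFrame(
            values, index=pd.Index(genes, name="gene_id"), columns=columns
        ),
        sample_meta=pd.DataFrame(
            meta_rows,
            index=pd.Index(columns, name="sample_id"),
            columns=["drug_id", "cell_line", "replicate"],
        ),
    )
    truth = SimulationTruth(
        programs=list(programs),
        collection=collection,
        noise_sd=noise_sd,
        cell_line_offset_sd=cell_line_offset_sd,
        seed=seed,
        cell_lines=cell_lines,
        null_drugs=null_drugs,
    )
    return expr, truth


def planted_recovery_report(
    recovered: dict, truth: SimulationTruth, panel_tfs: list | None = None
) -> dict:
    """Compare recovered activation states with the planted programs.

    ``recovered`` maps drug id -> {tf -> state}.  A planted (drug, TF)
    effect counts as recovered only with the correct sign; an excluded call
    is a miss, a nonzero call on an untouched TF (or the wrong sign) is a
    false positive.  Also reports the Spearman correlation between planted
    and recovered pro-differentiation scores (over ``panel_tfs`` when
    given, else all TFs).
    """
    from scipy.stats import spearmanr

    from .scoring import prodiff_score

    planted = truth.planted_states()
    missing = set(planted) - set(recovered)
    extra = set(recovered) - set(planted)
    if missing or extra:
        raise ValueError(
            f"drug ids mismatch: missing {sorted(missing)[:5]}, "
            f"unexpected {sorted(extra)[:5]}"
        )
    tp = fp = fn = 0
    per_drug = {}
    planted_scores, recovered_scores = [], []
    for drug, true_states in planted.items():
        rec = recovered[drug]
        d_tp = d_fp = d_fn = 0
        for tf, true_state in true_states.items():
            r = rec.get(tf, 0)
            called = r in (1, -1)
            if true_state != 0:
                if r == true_state:
                    d_tp += 1
                else:
                    d_fn += 1
                    if called:
                        d_fp += 1
            elif called:
                d_fp += 1
        tp, fp, fn = tp + d_tp, fp + d_fp, fn + d_fn
        per_drug[drug] = {"tp": d_tp, "fp": d_fp, "fn": d_fn}
        tfs = panel_tfs if panel_tfs is not None else sorted(true_states)
        planted_scores.append(
            sum(true_states[t] for t in tfs if true_states.get(t) in (1, -1))
        )
        recovered_scores.append(prodiff_score([rec.get(t, 0) for t in tfs]))
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    if len(set(planted_scores)) > 1 and len(set(recovered_scores)) > 1:
        rho = float(spearmanr(planted_scores, recovered_scores).statistic)
    else:
        rho = float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "score_spearman": rho,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "per_drug": per_drug,
    }
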
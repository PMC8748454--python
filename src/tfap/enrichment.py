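"""TF-target enrichment, rank integration and activation-state calls.

For one gene list (up- or down-regulated genes of a drug) and one library,
every TF is scored by the hypergeometric upper-tail probability of the
overlap between its target set and the gene list, drawn against the shared
background universe.  TFs are ranked by ascending p within each library and
the per-library ranks are combined by their arithmetic mean (MeanRank).

Because mean ranks have no natural p-value, significance uses an empirical
threshold: in each library, note the deepest rank whose enrichment p is
still below ``alpha``; average those positions over libraries; call a TF
significant when its mean rank does not exceed that average threshold
position.  A TF significant for both the up- and the down-list is excluded
from further interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np
from scipy import stats

from .libraries import LibraryCollection, TFLibrary

# Signed activation states. EXCLUDED marks a TF enriched in both the up- and
# the down-list; downstream scoring ignores it exactly like UNCHANGED.
ACTIVATED = 1
REPRESSED = -1
UNCHANGED = 0
EXCLUDED = 2

STATE_LABELS = {
    ACTIVATED: "activated",
    REPRESSED: "repressed",
    UNCHANGED: "unchanged",
    EXCLUDED: "excluded",
}


@dataclass(frozen=True)
class EnrichmentRecord:
    tf_id: str
    library_name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p: float
    rank: int = 0


def hypergeometric_enrichment(
    gene_list: set | frozenset,
    tf_targets: set | frozenset,
    universe: set | frozenset,
) -> tuple[float, int, float]:
    """Upper-tail hypergeometric overlap test.

    Returns ``(p, overlap, odds_ratio)`` where ``p = P[X >= overlap]`` for
    ``X`` the overlap when ``len(gene_list)`` genes are drawn without
    replacement from the universe, of which ``len(tf_targets)`` are targets.
    """
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    tf_targets = set(tf_targets)
    if not gene_list <= set(universe):
        raise ValueError("gene list not contained in universe")
    if not tf_targets <= set(universe):
        raise ValueError("target set not contained in universe")
    n, K = len(gene_list), len(tf_targets)
    k = len(gene_list & tf_targets)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(p, 1.0)
    # Haldane-corrected odds ratio of the 2x2 overlap table
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return p, k, odds


def rank_tfs_per_library(
    gene_list: set | frozenset, lib: TFLibrary
) -> list[EnrichmentRecord]:
    """Enrich every TF of one library and rank by ascending p.

    Ties break by larger overlap, then lexicographic TF id, so the ranking
    is a deterministic permutation of 1..n_tfs.  An empty gene list is
    legal: every p is 1 and the ranking degenerates to the tie-break order.
    """
    N = len(lib.universe)
    gene_list = set(gene_list) & set(lib.universe)
    n = len(gene_list)
    tf_ids = lib.tf_ids
    K = np.array([len(lib.sets[tf]) for tf in tf_ids])
    k = np.array([len(gene_list & lib.sets[tf]) for tf in tf_ids])
    p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.minimum(p, 1.0)
    order = sorted(
        range(len(tf_ids)), key=lambda i: (p[i], -k[i], tf_ids[i])
    )
    return [
        EnrichmentRecord(
            tf_id=tf_ids[i],
            library_name=lib.name,
            overlap=int(k[i]),
            list_size=n,
            set_size=int(K[i]),
            universe_size=N,
            p=float(p[i]),
            rank=r,
        )
        for r, i in enumerate(order, start=1)
    ]


def enrich_collection(
    gene_list: set | frozenset, collection: LibraryCollection
) -> dict:
    """Per-library rankings for one gene list: name -> ranked records."""
    return {lib.name: rank_tfs_per_library(gene_list, lib) for lib in collection}


def mean_rank_integrate(
    per_library_rankings: dict, missing: str = "penalize"
) -> dict:
    """Combine per-library rankings into one mean rank per TF.

    ``missing="penalize"`` assigns a TF absent from a library the rank
    ``n_tfs_of_that_library + 1`` (absence is evidence against, but finite);
    ``missing="present_only"`` averages only over libraries containing the
    TF.
    """
    if not per_library_rankings:
        raise ValueError("need at least one library ranking")
    if missing not in ("penalize", "present_only"):
        raise ValueError(f"unknown missing-TF rule {missing!r}")
    lib_sizes = {
        name: len(records) for name, records in per_library_rankings.items()
    }
    ranks: dict = {}
    for name, records in per_library_rankings.items():
        for rec in records:
            ranks.setdefault(rec.tf_id, {})[name] = rec.rank
    out = {}
    for tf, by_lib in ranks.items():
        vals = []
        for name, size in lib_sizes.items():
            if name in by_lib:
                vals.append(by_lib[name])
            elif missing == "penalize":
                vals.append(size + 1)
        out[tf] = fmean(vals)
    return out


def empirical_threshold(
    per_library_rankings: dict, alpha: float = 0.05
) -> tuple[dict, float]:
    """Per-library last-significant rank positions and their average.

    In a p-ascending ranking the positions with ``p < alpha`` form a prefix,
    so the threshold is simply the deepest such position (0 when no TF is
    significant in that library).
    """
    if not per_library_rankings:
        raise ValueError("need at least one library ranking")
    positions = {}
    for name, records in per_library_rankings.items():
        pos = 0
        for rec in records:
            if rec.p < alpha:
                pos = max(pos, rec.rank)
        positions[name] = pos
    avg = fmean(positions.values())
    return positions, avg


def call_significant(
    mean_ranks: dict, avg_threshold: float, inclusive: bool = True
) -> frozenset:
    """TFs whose mean rank clears the average threshold position.

    Rank 1 is the strongest enrichment, so "above the threshold position"
    means numerically smaller-or-equal mean rank.  The boundary is closed by
    default (``inclusive=True``).
    """
    if avg_threshold < 0:
        raise ValueError("avg_threshold must be >= 0")
    if inclusive:
        return frozenset(t for t, r in mean_ranks.items() if r <= avg_threshold)
    return frozenset(t for t, r in mean_ranks.items() if r < avg_threshold)


def significant_tfs(
    gene_list: set | frozenset,
    collection: LibraryCollection,
    alpha: float = 0.05,
    missing: str = "penalize",
    inclusive: bool = True,
) -> frozenset:
    """Full enrichment path for one gene list: rank, integrate, threshold."""
    rankings = enrich_collection(gene_list, collection)
    mean_ranks = mean_rank_integrate(rankings, missing=missing)
    _, avg = empirical_threshold(rankings, alpha=alpha)
    return call_significant(mean_ranks, avg, inclusive=inclusive)


def call_activation_states(
    sig_up: set | frozenset, sig_down: set | frozenset, tf_union: set | frozenset
) -> dict:
    """Signed state per TF: +1 up-only, -1 down-only, EXCLUDED both, else 0."""
    sig_up, sig_down = set(sig_up), set(sig_down)
    stray = (sig_up | sig_down) - set(tf_union)
    if stray:
        raise ValueError(f"significant TFs outside the TF union: {sorted(stray)[:5]}")
    states = {}
    for tf in tf_union:
        in_up, in_down = tf in sig_up, tf in sig_down
        if in_up and in_down:
            states[tf] = EXCLUDED
        elif in_up:
            states[tf] = ACTIVATED
        elif in_down:
            states[tf] = REPRESSED
        else:
            states[tf] = UNCHANGED
    return states
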
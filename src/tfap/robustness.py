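"""Noise-robustness analysis of perturbation profiles.

The question: are per-drug profiles more reproducible across cell lines
when expressed as TF-activation vectors than as raw expression vectors?
Both profile sets are embedded in 2-D with tSNE; for every drug the
Euclidean distances between its points from different cell lines are
collected; the same is done after a within-profile feature randomization
that preserves each profile's value distribution but destroys gene
identity; and the observed-vs-randomized distance distributions are
compared with a two-sample Kolmogorov-Smirnov test.  A larger KS statistic
means the observed same-drug similarity stands further out of the noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.manifold import TSNE


@dataclass
class ProfileSet:
    """Profiles x features matrix with (drug, cell line) labels."""

    features: np.ndarray
    labels: list  # of (drug_id, cell_line) tuples
    space: str  # "expression" | "tf_activation"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("one label per profile required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate (drug, cell line) labels")

    @property
    def n_profiles(self) -> int:
        return self.features.shape[0]


def build_tf_feature_vectors(
    per_profile_values: dict, tf_order: list | None = None, feature: str = "state"
) -> ProfileSet:
    """One TF-space feature vector per (drug, cell line).

    ``per_profile_values`` maps (drug_id, cell_line) -> {tf -> value} where
    the value is a signed activation state (``feature="state"``, excluded
    cells mapped to 0) or a mean rank (``feature="rank"``, negated so that
    larger = more active).
    """
    if feature not in ("state", "rank"):
        raise ValueError(f"unknown feature kind {feature!r}")
    labels = list(per_profile_values)
    if not labels:
        raise ValueError("no profiles supplied")
    first = set(per_profile_values[labels[0]])
    if tf_order is None:
        tf_order = sorted(first)
    for lab in labels:
        if set(per_profile_values[lab]) != set(tf_order):
            raise ValueError(f"profile {lab} does not cover the common TF axis")
    rows = []
    for lab in labels:
        vals = per_profile_values[lab]
        if feature == "state":
            from .enrichment import EXCLUDED

            row = [0.0 if vals[tf] == EXCLUDED else float(vals[tf]) for tf in tf_order]
        else:
            row = [-float(vals[tf]) for tf in tf_order]
        rows.append(row)
    return ProfileSet(
        features=np.array(rows), labels=labels, space="tf_activation"
    )


def build_expression_profiles(expr) -> ProfileSet:
    """Mean treated expression per (drug, cell line) as one profile each."""
    labels, rows = [], []
    for cl in expr.cell_lines:
        for drug in expr.drugs(cl):
            cols = expr.samples_for(drug, cl)
            rows.append(expr.values[cols].mean(axis=1).to_numpy())
            labels.append((drug, cl))
    return ProfileSet(features=np.array(rows), labels=labels, space="expression")


def tf_profiles_from_screens(screens: dict, tf_union) -> ProfileSet:
    """TF-state profiles per (drug, cell line) from per-cell-line screens.

    ``screens`` maps cell line -> ScreenResult.  Drugs that were not
    analysable in a cell line contribute an all-zero profile, keeping the
    label sets of the two spaces aligned.
    """
    zero = {tf: 0 for tf in tf_union}
    per_profile = {}
    for cl, res in screens.items():
        drugs = set(res.states) | set(res.skipped)
        for drug in drugs:
            per_profile[(drug, cl)] = res.states.get(drug, zero)
    return build_tf_feature_vectors(per_profile, tf_order=sorted(tf_union))


def max_feasible_perplexity(n_profiles: int) -> float:
    return (n_profiles - 1) / 3.0


def tsne_embed(
    profiles: ProfileSet, perplexity: float | None = None, seed: int = 0
) -> np.ndarray:
    """Seeded 2-D tSNE embedding (random initialization, fixed seed)."""
    n = profiles.n_profiles
    if n < 4:
        raise ValueError("need at least 4 profiles for a tSNE embedding")
    limit = max_feasible_perplexity(n)
    if perplexity is None:
        perplexity = min(30.0, math.floor(limit * 100) / 100 - 1e-9)
        perplexity = max(perplexity, 1.0)
    if perplexity >= limit:
        raise ValueError(
            f"perplexity {perplexity} infeasible for {n} profiles; "
            f"must be < {limit:.2f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="random",
        random_state=seed,
        method="exact" if n < 50 else "barnes_hut",
    )
    return tsne.fit_transform(profiles.features)


def same_drug_distances(
    embedding: np.ndarray, labels: list, normalize: bool = False
) -> np.ndarray:
    """Distances between same-drug points from different cell lines.

    Every unordered pair of profiles sharing a drug id but differing in
    cell line contributes one Euclidean distance.  With ``normalize=True``
    distances are expressed in units of the mean distance over *all* point
    pairs of the embedding; a tSNE map has no intrinsic scale, so
    comparisons between two separately fitted maps need this
    normalization.
    """
    embedding = np.asarray(embedding, dtype=float)
    by_drug: dict = {}
    for idx, (drug, cl) in enumerate(labels):
        by_drug.setdefault(drug, []).append((idx, cl))
    dists = []
    for drug, members in by_drug.items():
        for (i, ci), (j, cj) in itertools.combinations(members, 2):
            if ci != cj:
                dists.append(float(np.linalg.norm(embedding[i] - embedding[j])))
    if not dists:
        raise ValueError("no drug is profiled in more than one cell line")
    dists_arr = np.array(dists)
    if normalize:
        n = embedding.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        scale = float(
            np.mean(np.linalg.norm(embedding[ii] - embedding[jj], axis=1))
        )
        if scale == 0:
            raise ValueError("degenerate embedding: all points coincide")
        dists_arr = dists_arr / scale
    return dists_arr


def randomize_profiles(profiles: ProfileSet, seed: int) -> ProfileSet:
    """Permute feature values independently within each profile.

    Preserves every profile's value multiset (hence its marginal
    distribution) while destroying which gene/TF carries which value —
    the null against which observed same-drug similarity is judged.
    """
    rng = np.random.default_rng(seed)
    shuffled = profiles.features.copy()
    for i in range(shuffled.shape[0]):
        rng.shuffle(shuffled[i])
    return replace(profiles, features=shuffled)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| evaluated at the pooled sample points."""
    a, b = np.sort(a), np.sort(b)
    pts = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pts, side="right") / a.size
    cdf_b = np.searchsorted(b, pts, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n1: int
    n2: int
    method: str


def ks_two_sample(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "asymp",
    seed: int | None = None,
    n_permutations: int = 10000,
    max_exact: int = 200000,
) -> KSResult:
    """Two-sided two-sample KS test.

    ``method="asymp"`` uses the Kolmogorov limiting distribution;
    ``method="permutation"`` estimates p over group-label permutations —
    exhaustively when C(n1+n2, n1) <= ``max_exact``, otherwise by a seeded
    Monte-Carlo sample of ``n_permutations`` splits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    D = _ks_statistic(a, b)
    if method == "asymp":
        p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
    elif method == "permutation":
        pooled = np.concatenate([a, b])
        n1, ntot = a.size, a.size + b.size
        tol = 1e-12
        if math.comb(ntot, n1) <= max_exact:
            count = total = 0
            for idx in itertools.combinations(range(ntot), n1):
                mask = np.zeros(ntot, dtype=bool)
                mask[list(idx)] = True
                d = _ks_statistic(pooled[mask], pooled[~mask])
                count += d >= D - tol
                total += 1
            p = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(ntot)
                d = _ks_statistic(pooled[perm[:n1]], pooled[perm[n1:]])
                count += d >= D - tol
            p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(D=D, p=min(float(p), 1.0), n1=int(a.size), n2=int(b.size), method=method)


def observed_vs_random_ks(
    profiles: ProfileSet,
    seed: int,
    perplexity: float | None = None,
    ks_method: str = "asymp",
    in_embedding: bool = True,
    normalize: bool = True,
) -> dict:
    """Embed, measure same-drug distances, repeat on randomized profiles, KS.

    Distances are normalized to each map's mean pairwise distance by
    default (tSNE scale is arbitrary and differs between the observed and
    randomized fits).  ``in_embedding=False`` measures distances in the
    original feature space instead of the 2-D map (sensitivity analysis).
    """
    rnd = randomize_profiles(profiles, seed=seed + 1)
    if in_embedding:
        emb_obs = tsne_embed(profiles, perplexity=perplexity, seed=seed)
        emb_rnd = tsne_embed(rnd, perplexity=perplexity, seed=seed)
    else:
        emb_obs, emb_rnd = profiles.features, rnd.features
    d_obs = same_drug_distances(emb_obs, profiles.labels, normalize=normalize)
    d_rnd = same_drug_distances(emb_rnd, rnd.labels, normalize=normalize)
    ks = ks_two_sample(d_obs, d_rnd, method=ks_method, seed=seed + 2)
    return {
        "space": profiles.space,
        "seed": seed,
        "observed": d_obs,
        "randomized": d_rnd,
        "ks": ks,
    }


def robustness_report(
    expr_profiles: ProfileSet,
    tf_profiles: ProfileSet,
    seed: int,
    perplexity: float | None = None,
    ks_method: str = "asymp",
    in_embedding: bool = True,
    normalize: bool = True,
) -> dict:
    """Paired observed-vs-random KS results for both profile spaces."""
    if set(expr_profiles.labels) != set(tf_profiles.labels):
        diff = set(expr_profiles.labels) ^ set(tf_profiles.labels)
        raise ValueError(
            f"profile sets label different (drug, cell line) pairs: {sorted(diff)[:5]}"
        )
    return {
        "expression": observed_vs_random_ks(
            expr_profiles, seed, perplexity, ks_method, in_embedding, normalize
        ),
        "tf_activation": observed_vs_random_ks(
            tf_profiles, seed, perplexity, ks_method, in_embedding, normalize
        ),
        "seed": seed,
    }


def knn_label_purity(embedding: np.ndarray, labels: list, k: int = 1) -> float:
    """Fraction of points whose k nearest neighbours share their label."""
    emb = np.asarray(embedding, dtype=float)
    labels = list(labels)
    n = emb.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    hits = 0.0
    for i in range(n):
        nn = np.argsort(d2[i], kind="stable")[:k]
        hits += np.mean([labels[j] == labels[i] for j in nn])
    return hits / n
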
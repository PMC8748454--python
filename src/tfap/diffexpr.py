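"""Empirical-Bayes moderated differential expression.

Each drug is contrasted against the pooled vehicle controls of the same cell
line with a two-sample moderated t-statistic: per-gene sample variances are
shrunk toward a common prior by the standard empirical-Bayes scheme,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

where ``d`` is the residual degrees of freedom of the contrast and the prior
``(d0, s0^2)`` is estimated from the distribution of per-gene log-variances
by method of moments (moments of ``log s^2`` under the scaled-F sampling
model, inverted through the trigamma function).  The moderated t is referred
to a t distribution on ``d0 + d`` degrees of freedom and p-values are
adjusted by Benjamini-Hochberg.

Significant up/down gene lists are then compiled with explicit, recorded
thresholds; a drug whose lists are both empty is simply not analysable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expression import CONTROL, ExpressionMatrix

#: Cap on the estimated prior degrees of freedom; beyond this the prior is
#: effectively infinite and the cap only guards floating-point overflow.
D0_CAP = 1e6


class InestimableContrastError(ValueError):
    """Too few samples to estimate the treated-vs-control contrast."""


class ZeroVarianceError(ValueError):
    """Zero residual variance with no prior to moderate it (d0 = 0)."""


@dataclass
class GeneLists:
    """Significantly up- and down-regulated genes for one drug."""

    drug_id: str
    up: frozenset
    down: frozenset
    alpha: float
    lfc_min: float
    universe_size: int

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down lists overlap")

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down)

    def is_analysable(self, min_list_size: int = 1) -> bool:
        """Whether the drug yielded enough modulated genes to screen."""
        return self.n_total >= min_list_size


def trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges from the
    asymptotic starting value ``1/x`` in a handful of steps.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("trigamma_inverse requires positive input")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-10:
            break
    return y if y.shape != (1,) else float(y[0])


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior.

    Under the sampling model, ``log s^2`` is a shifted log-F variable;
    matching its mean and variance through digamma/trigamma moments yields
    the prior degrees of freedom ``d0`` and prior variance ``s0^2``.
    Infinite estimates are capped at :data:`D0_CAP`.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ZeroVarianceError(
            "cannot estimate a variance prior: fewer than two genes with "
            "positive residual variance"
        )
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * float(trigamma_inverse(evar))
        if d0 > D0_CAP:
            warnings.warn(f"prior df estimate exceeds cap, using d0={D0_CAP:g}")
            d0 = D0_CAP
        s02 = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        # observed log-variances underdispersed relative to pure sampling
        # noise: the prior is effectively infinitely informative
        d0 = D0_CAP
        s02 = float(np.exp(np.mean(e)))
    return d0, s02


def moderated_t_contrast(
    expr: ExpressionMatrix,
    drug_id: str,
    cell_line: str,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated-t contrast of one drug against same-cell-line controls.

    Parameters
    ----------
    prior_df, prior_var
        Override the empirical-Bayes prior.  ``prior_df=0`` gives the
        ordinary pooled two-sample t; a very large ``prior_df`` with a
        ``prior_var`` gives the fully shrunk limit.

    Returns
    -------
    DataFrame indexed by gene id with columns ``log_fc``, ``t_mod``,
    ``p_raw``, ``p_adj``, ``df_total`` and boolean attr ``singleton_treated``
    set when the treated group has a single sample.
    """
    trt = expr.samples_for(drug_id, cell_line)
    ctl = expr.samples_for(CONTROL, cell_line)
    n1, n2 = len(trt), len(ctl)
    if n1 < 1:
        raise InestimableContrastError(
            f"drug {drug_id!r} has no samples in cell line {cell_line!r}"
        )
    if n2 < 2:
        raise InestimableContrastError(
            f"drug {drug_id!r}: need >=2 control samples in cell line "
            f"{cell_line!r}, found {n2}"
        )
    d = (n1 - 1) + (n2 - 1)
    if d < 1:
        raise InestimableContrastError(
            f"drug {drug_id!r}: zero residual degrees of freedom"
        )

    x1 = expr.values[trt].to_numpy(dtype=float)
    x2 = expr.values[ctl].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log_fc = m1 - m2
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = (ss1 + ss2) / d

    degenerate = False
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
        if d0 == 0:
            if np.any(s2 == 0):
                raise ZeroVarianceError(
                    f"drug {drug_id!r}: zero-variance genes with prior_df=0 "
                    "would divide by zero"
                )
            s02 = 0.0
        else:
            s02 = (
                float(prior_var)
                if prior_var is not None
                else estimate_variance_prior(s2, d)[1]
            )
    else:
        try:
            d0, s02 = estimate_variance_prior(s2, d)
        except ZeroVarianceError:
            # noise-free data: every gene separates perfectly or not at all
            degenerate = True
            d0, s02 = 0.0, 0.0

    if degenerate:
        t_mod = np.sign(log_fc) * np.where(log_fc == 0.0, 0.0, np.inf)
        p_raw = np.where(log_fc == 0.0, 1.0, 0.0)
        df_total = float(d)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        if np.any(s2_post == 0):
            raise ZeroVarianceError(
                f"drug {drug_id!r}: moderated variance is zero for some genes"
            )
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t_mod = log_fc / se
        df_total = d0 + d
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    p_adj = benjamini_hochberg(p_raw)
    out = pd.DataFrame(
        {
            "log_fc": log_fc,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "df_total": float(df_total),
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    out.attrs["drug_id"] = drug_id
    out.attrs["cell_line"] = cell_line
    out.attrs["singleton_treated"] = n1 == 1
    out.attrs["d0"] = float(d0)
    out.attrs["s02"] = float(s02)
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment (delegates to statsmodels)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def derive_gene_lists(
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    drug_id: str | None = None,
) -> GeneLists:
    """Split a contrast table into significant up/down gene sets.

    up = {p_adj < alpha and log_fc >= +lfc_min};
    down = {p_adj < alpha and log_fc <= -lfc_min}.  Empty lists are a valid
    outcome: the drug is then not analysable, mirroring the attrition from a
    full compound panel to the subset with a detectable signature.
    """
    if contrasts.empty:
        raise ValueError("contrast table is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    sig = contrasts["p_adj"] < alpha
    lfc = contrasts["log_fc"]
    # a gene with log_fc == 0 never enters either list, even at lfc_min == 0
    up = frozenset(contrasts.index[sig & (lfc > 0) & (lfc >= lfc_min)])
    down = frozenset(contrasts.index[sig & (lfc < 0) & (-lfc >= lfc_min)])
    return GeneLists(
        drug_id=drug_id or contrasts.attrs.get("drug_id", "?"),
        up=up,
        down=down,
        alpha=alpha,
        lfc_min=lfc_min,
        universe_size=len(contrasts),
    )


def write_gene_lists(lists: GeneLists, path) -> None:
    """Two-column TSV (gene_id, direction) for one drug."""
    with open(path, "w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sorted(lists.up):
            fh.write(f"{g}\tup\n")
        for g in sorted(lists.down):
            fh.write(f"{g}\tdown\n")
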
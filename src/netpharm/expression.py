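"""Normalization, empirical-Bayes moderated t-tests, FDR and over-expression calls.

The differential-expression model is the standard two-group empirical-Bayes
moderated t. Per probe g, with pooled two-sample variance ``s_g^2`` on
``d_g = n1 + n2 - 2`` degrees of freedom, the variance is shrunk toward a
prior ``s0^2`` with prior degrees of freedom ``d0``::

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t~_g   = (mean_case - mean_ref) / (s~_g * sqrt(1/n1 + 1/n2))

and the two-sided p-value comes from a t distribution on ``d0 + d_g``
degrees of freedom. ``(d0, s0^2)`` are fitted by matching the first two
moments of ``log s_g^2`` to the scaled-F distribution implied by the model;
with ``d0 = 0`` the statistic reduces exactly to the ordinary pooled-variance
two-sample t-test.

False-discovery control is Benjamini-Hochberg step-up; a gene is called
over-expressed if *any* of its probes is significant with positive fold
change (all probes of a gene are considered, none pre-selected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .config import ComparisonSpec, ConfigError

logger = logging.getLogger("netpharm.expression")

__all__ = [
    "normalize",
    "fit_variance_prior",
    "moderated_ttest",
    "adjust_bh",
    "GeneCallSet",
    "call_overexpressed",
    "intersect_common",
]


def normalize(matrix: pd.DataFrame, mode: str = "zscore_rows") -> pd.DataFrame:
    """Standardize a probe x sample log2-intensity matrix.

    Parameters
    ----------
    matrix
        Probes in rows, samples in columns.
    mode
        ``"zscore_rows"`` -- each probe row to mean 0, sample SD 1
        (per-gene standardization across the cohort);
        ``"center_scale"`` -- each sample column to mean 0, sample SD 1
        (makes per-array distributions comparable).

    Rows (or columns) with zero variance cannot be standardized and are
    dropped with a logged warning rather than aborting the run.
    """
    if matrix.shape[1] < 2:
        raise ValueError("normalize requires at least 2 samples")
    if mode == "zscore_rows":
        sd = matrix.std(axis=1, ddof=1)
        bad = sd == 0
        if bad.any():
            logger.warning(
                "normalize: dropping %d zero-variance probe row(s): %s",
                int(bad.sum()), ", ".join(map(str, matrix.index[bad][:10])),
            )
            matrix = matrix.loc[~bad]
            sd = sd[~bad]
        return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)
    if mode == "center_scale":
        sd = matrix.std(axis=0, ddof=1)
        bad = sd == 0
        if bad.any():
            logger.warning(
                "normalize: dropping %d zero-variance sample column(s): %s",
                int(bad.sum()), ", ".join(map(str, matrix.columns[bad][:10])),
            )
            matrix = matrix.loc[:, ~bad]
            sd = sd[~bad]
        return matrix.sub(matrix.mean(axis=0), axis=1).div(sd, axis=1)
    raise ValueError(f"unknown normalization mode: {mode!r}")


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on y -> trigamma(y); monotone decreasing, so the
    # damped update below converges from the asymptotic starting point.
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the variance prior ``(d0, s0^2)`` by moments on log sample variances.

    Under the hierarchical model, ``s_g^2`` follows ``s0^2`` times an F
    distribution on ``(df, d0)`` degrees of freedom; the mean and variance of
    ``log s_g^2`` are closed forms in digamma/trigamma functions, so matching
    empirical moments gives ``d0`` via a trigamma inverse. When the observed
    spread of log variances is no larger than expected from sampling alone,
    ``d0`` is infinite and every probe shares ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.all():
        logger.warning("fit_variance_prior: excluding %d zero variance(s) from the moment fit",
                       int((~pos).sum()))
    s2 = s2[pos]
    if s2.size < 2:
        raise ValueError("fit_variance_prior needs >= 2 positive sample variances")
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_ttest(
    matrix: pd.DataFrame,
    annot: pd.DataFrame | pd.Series,
    spec: ComparisonSpec,
    *,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated two-sample t-test for one comparison.

    Parameters
    ----------
    matrix
        Probe x sample log2 intensities.
    annot
        Sample annotation: a DataFrame with ``sample_id``/``group`` columns or
        a Series mapping sample_id -> group.
    spec
        The contrast; each side must have at least 2 samples.
    d0, s0_2
        Override the fitted prior. ``d0=0`` gives the ordinary pooled-variance
        t-test (``s0_2`` is then ignored); ``d0=inf`` requires ``s0_2``.

    Returns
    -------
    DataFrame indexed by probe with columns ``lfc`` (case mean - reference
    mean), ``t``, ``p`` (two-sided), ``q`` (BH), ``s2`` (pooled sample
    variance) and ``df`` (residual d_g). The fitted prior is stored in
    ``.attrs`` (``d0``, ``s0_2``, ``comparison``, ``n_case``, ``n_ref``).
    """
    groups = _group_series(annot)
    case_samples = [s for s in matrix.columns if groups.get(s) in set(spec.case)]
    ref_samples = [s for s in matrix.columns if groups.get(s) in set(spec.reference)]
    n1, n2 = len(case_samples), len(ref_samples)
    if n1 < 2 or n2 < 2:
        raise ConfigError(
            f"comparison '{spec.name}': needs >= 2 samples per side (got {n1} case, {n2} reference)"
        )
    x1 = matrix[case_samples].to_numpy(dtype=float)
    x2 = matrix[ref_samples].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m1 - m2
    dg = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg

    if d0 is None:
        d0, s0_2 = fit_variance_prior(s2, dg)
    elif np.isinf(d0):
        if s0_2 is None:
            raise ValueError("d0=inf requires an explicit s0_2")
    elif d0 < 0:
        raise ValueError("d0 must be >= 0")

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = float(dg)
    else:
        s2_tilde = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(lfc)
    ok = se > 0
    t[ok] = lfc[ok] / se[ok]
    degenerate = ~ok & (lfc != 0)
    if degenerate.any():
        logger.warning(
            "moderated_ttest[%s]: %d probe(s) with zero moderated variance and nonzero "
            "mean difference; statistic set to +/-inf",
            spec.name, int(degenerate.sum()),
        )
        t[degenerate] = np.sign(lfc[degenerate]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # keep p strictly positive so downstream log/threshold logic stays defined
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0)
    q = adjust_bh(p)

    de = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q, "s2": s2, "df": float(dg)},
        index=matrix.index.copy(),
    )
    de.attrs.update(
        comparison=spec.name, d0=float(d0), s0_2=(None if s0_2 is None else float(s0_2)),
        n_case=n1, n_ref=n2,
    )
    return de


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    For sorted p-values ``p_(1) <= ... <= p_(m)``,
    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, returned in the
    original input order. Monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class GeneCallSet:
    """Gene-level over-expression calls for one comparison.

    ``called`` holds genes with at least one significant, positively regulated
    probe; ``best`` carries, for *every* measured gene, the representative
    probe (smallest q; ties by largest \\|lfc\\|, then probe id) used when
    annotating network nodes.
    """

    comparison: str
    called: set[str] = field(default_factory=set)
    best: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05
    min_lfc: float = 0.0


def call_overexpressed(
    de: pd.DataFrame,
    probe_map: pd.DataFrame,
    alpha: float = 0.05,
    min_lfc: float = 0.0,
) -> GeneCallSet:
    """Aggregate probe-level statistics to gene-level over-expression calls.

    A gene is called if ANY of its probes has ``q < alpha`` and
    ``lfc > min_lfc``; all probes of a gene participate. Probes absent from
    the probe map are dropped with a warning.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    pm = probe_map[["probe_id", "gene_symbol"]].drop_duplicates()
    table = de.copy()
    table.index.name = "probe_id"
    table = table.reset_index().merge(pm, on="probe_id", how="left")
    unmapped = table["gene_symbol"].isna()
    if unmapped.any():
        logger.warning("call_overexpressed: dropping %d probe(s) missing from the probe map",
                       int(unmapped.sum()))
        table = table[~unmapped]
    table["pass"] = (table["q"] < alpha) & (table["lfc"] > min_lfc)
    called = set(table.loc[table["pass"], "gene_symbol"])

    table["_neg_abs_lfc"] = -table["lfc"].abs()
    best = (
        table.sort_values(["q", "_neg_abs_lfc", "probe_id"], kind="mergesort")
        .groupby("gene_symbol", sort=True)
        .first()[["probe_id", "lfc", "t", "p", "q"]]
    )
    best["called"] = best.index.isin(called)
    comparison = de.attrs.get("comparison", "")
    return GeneCallSet(comparison=comparison, called=called, best=best,
                       alpha=alpha, min_lfc=min_lfc)


def intersect_common(call_sets: list[GeneCallSet]) -> set[str]:
    """Genes called over-expressed in every comparison (the common set)."""
    if len(call_sets) < 2:
        raise ValueError("intersect_common requires >= 2 call sets")
    common = set(call_sets[0].called)
    for cs in call_sets[1:]:
        common &= cs.called
    return common


def _group_series(annot: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(annot, pd.Series):
        return annot
    return annot.set_index("sample_id")["group"]
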
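"""Normalization and differential statistics for the paired islet design.

Sample effects are removed by Tukey two-way median polish on the log2
matrix (only the column effect is subtracted, so between-proteoform
structure is preserved).  Differential abundance on the paired design is a
one-sample empirical-Bayes moderated t-test on per-donor log2 differences
(treated - control): per-proteoform variances s_g^2 with residual degrees
of freedom d_g = n_pairs - 1 are shrunk toward a prior (d0, s0^2) estimated
by moment matching on log s_g^2 under the scaled chi-square model
(digamma/trigamma relations); the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t = mean / (s~_g / sqrt(n)) is referred to a t distribution on
d0 + d_g degrees of freedom.  P values are Benjamini-Hochberg adjusted.
Proteoforms observed in only one condition group are tested for
group-restricted presence with an exact hypergeometric probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .core import SampleDesign
from .regions import RegionMap, annotate_region

logger = logging.getLogger("proformquant")

#: cap representing an effectively infinite prior df
D0_CAP = 1e6


# ---------------------------------------------------------------------------
# Median polish normalization


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    normalized: pd.DataFrame
    n_iter: int
    converged: bool


def median_polish(matrix: pd.DataFrame, tol: float = 1e-6,
                  max_iter: int = 50) -> MedianPolishResult:
    """Tukey two-way median polish with missing cells skipped.

    Decomposes ``x[i,j] = overall + row[i] + col[j] + residual[i,j]``;
    the normalized matrix is the original minus the column (sample) effect.
    All-missing rows/columns are dropped with a warning.
    """
    x = matrix.astype(float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("median polish needs at least a 2x2 matrix")
    bad_rows = x.index[x.isna().all(axis=1)]
    bad_cols = x.columns[x.isna().all(axis=0)]
    if len(bad_rows) or len(bad_cols):
        logger.warning("median polish: dropping %d all-missing rows, "
                       "%d all-missing columns", len(bad_rows), len(bad_cols))
        x = x.drop(index=bad_rows, columns=bad_cols)
    z = x.to_numpy(copy=True)
    row = np.zeros(z.shape[0])
    col = np.zeros(z.shape[1])
    overall = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta_max = 0.0
        rmed = np.nanmedian(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        delta_max = max(delta_max, np.max(np.abs(rmed), initial=0.0))
        cshift = np.median(col)
        col -= cshift
        overall += cshift
        cmed = np.nanmedian(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        delta_max = max(delta_max, np.max(np.abs(cmed), initial=0.0))
        rshift = np.median(row)
        row -= rshift
        overall += rshift
        if delta_max < tol:
            converged = True
            break
    residuals = pd.DataFrame(z, index=x.index, columns=x.columns)
    col_effects = pd.Series(col, index=x.columns, name="col_effect")
    normalized = x.sub(col_effects, axis=1)
    return MedianPolishResult(
        overall=float(overall),
        row_effects=pd.Series(row, index=x.index, name="row_effect"),
        col_effects=col_effects,
        residuals=residuals, normalized=normalized,
        n_iter=it, converged=converged)


# ---------------------------------------------------------------------------
# Paired differences


def paired_log2fc(matrix: pd.DataFrame, design: SampleDesign,
                  min_pairs: int = 2):
    """Per-donor treated - control log2 differences per proteoform.

    Proteoforms with fewer than ``min_pairs`` complete donor pairs are
    excluded (the quantifiability filter).  Returns ``(diffs, n_excluded)``
    where ``diffs`` is a proteoform x donor frame of differences (NaN where
    the pair is incomplete).
    """
    pairs = design.complete_pairs()
    if not pairs:
        raise ValueError("design has no complete donor pairs")
    donors = [p[0] for p in pairs]
    diffs = pd.DataFrame(
        {donor: matrix[treated] - matrix[control]
         for donor, control, treated in pairs},
        index=matrix.index)[donors]
    n_complete = diffs.notna().sum(axis=1)
    keep = n_complete >= min_pairs
    n_excluded = int((~keep).sum())
    return diffs[keep], n_excluded


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t


@dataclass
class EBParams:
    """Hyperparameters of the scaled chi-square variance prior."""

    d0: float          # prior degrees of freedom (capped at D0_CAP)
    s0_sq: float       # prior variance

    @property
    def finite(self) -> bool:
        return self.d0 < D0_CAP


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, df: np.ndarray) -> EBParams:
    """Moment-match (d0, s0^2) on z = log s_g^2.

    Under the hierarchical model, e_g = z_g - digamma(d_g/2) + log(d_g/2)
    has mean log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(d_g/2) + trigamma(d0/2); solving the trigamma relation gives
    d0, then s0^2 from the mean.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    s_sq, df = s_sq[ok], df[ok]
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(
        np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = min(2.0 * trigamma_inverse(evar), D0_CAP)
        s0_sq = float(np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s0_sq = float(np.exp(emean))
    return EBParams(d0=d0, s0_sq=s0_sq)


def moderated_t(diffs: pd.DataFrame, d0: float | None = None,
                s0_sq: float | None = None):
    """Empirical-Bayes moderated one-sample t-test on paired differences.

    ``diffs`` is proteoform x donor (NaN allowed).  With ``d0=0`` the test
    reduces exactly to the classical one-sample t.  When hyperparameters are
    not supplied they are estimated from the data.  Returns
    ``(EBParams, DataFrame)`` with columns n_pairs, log2fc, s_sq, t, p.
    """
    x = diffs.to_numpy(float)
    n = np.sum(np.isfinite(x), axis=1)
    if np.any(n < 2):
        raise ValueError("every proteoform needs >= 2 paired differences")
    mean = np.nanmean(x, axis=1)
    s_sq = np.nanvar(x, axis=1, ddof=1)
    d_g = n - 1.0
    if d0 is None:
        if len(diffs) < 2:
            raise ValueError("need >= 2 proteoforms to estimate the prior")
        params = fit_variance_prior(s_sq, d_g)
    else:
        params = EBParams(d0=float(d0),
                          s0_sq=float(s0_sq) if s0_sq is not None else 0.0)
    if params.d0 > 0:
        post_var = ((params.d0 * params.s0_sq + d_g * s_sq)
                    / (params.d0 + d_g))
    else:
        post_var = s_sq
    df_total = np.minimum(params.d0 + d_g, D0_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(post_var / n)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    zero_var = post_var == 0
    if zero_var.any():
        logger.warning("%d proteoforms have zero posterior variance; "
                       "p undefined", int(zero_var.sum()))
        p[zero_var] = np.nan
    result = pd.DataFrame({
        "n_pairs": n.astype(int), "log2fc": mean, "s_sq": s_sq,
        "t": t, "df": df_total, "p": p,
    }, index=diffs.index)
    return params, result


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(results: pd.DataFrame, p_cut: float = 0.05,
                     lfc_cut: float = 1.0) -> pd.Series:
    """Label each proteoform increased / decreased / null.

    increased: p < p_cut and log2fc > lfc_cut; decreased: p < p_cut and
    log2fc < -lfc_cut; otherwise null (boundaries are strict).
    """
    p = results["p"]
    lfc = results["log2fc"]
    out = pd.Series("null", index=results.index, name="class")
    out[(p < p_cut) & (lfc > lfc_cut)] = "increased"
    out[(p < p_cut) & (lfc < -lfc_cut)] = "decreased"
    return out


# ---------------------------------------------------------------------------
# Presence / absence (group-unique proteoforms)


@dataclass
class PresenceResult:
    label: str
    k: int                 # samples in which the proteoform is observed
    group: str             # condition containing all observations
    probability: float     # hypergeometric P(all k draws fall in the group)
    significant: bool


def presence_test(present: pd.Series, design: SampleDesign,
                  alpha: float = 0.01, label: str = "") -> PresenceResult | None:
    """Exact probability that all observations fall in one condition group.

    ``present`` is a boolean Series indexed by sample_id.  If observations
    occur in both groups (or none) the test is not applicable and None is
    returned.  probability = C(n_g, k) / C(N, k), the chance that k samples
    drawn uniformly without replacement from all N land in the group.
    """
    observed = [s for s in present.index if bool(present[s])]
    if not observed:
        return None
    groups = {design.condition_of(s) for s in observed}
    if len(groups) != 1:
        return None
    group = groups.pop()
    n_total = len(present.index)
    n_group = len(design.samples_in(group))
    k = len(observed)
    prob = float(special.comb(n_group, k, exact=True)
                 / special.comb(n_total, k, exact=True))
    return PresenceResult(label=label, k=k, group=group, probability=prob,
                          significant=prob < alpha)


def presence_screen(qm_presence: pd.DataFrame, design: SampleDesign,
                    alpha: float = 0.01) -> pd.DataFrame:
    """Run :func:`presence_test` over all proteoform rows; keep applicable ones."""
    rows = []
    for label, row in qm_presence.iterrows():
        res = presence_test(row, design, alpha=alpha, label=label)
        if res is not None:
            rows.append({"label": res.label, "k": res.k, "group": res.group,
                         "probability": res.probability,
                         "significant": res.significant})
    return pd.DataFrame(rows, columns=["label", "k", "group", "probability",
                                       "significant"])


# ---------------------------------------------------------------------------
# Regional trends


def regional_trend(results: pd.DataFrame, region_map: RegionMap, gene: str,
                   region: str) -> dict:
    """Counts of contained proteoforms by sign of log2 fold change.

    A proteoform counts toward the region only if its [first_aa, last_aa]
    interval is fully contained in it; zero fold changes count as neither
    up nor down.
    """
    reg = region_map.get(gene, region)  # KeyError for unknown region
    sub = results[results["gene"] == gene]
    contained = sub[(sub["first_aa"] >= reg.first_aa)
                    & (sub["last_aa"] <= reg.last_aa)]
    lfc = contained["log2fc"]
    return {"gene": gene, "region": region,
            "n_total": int(len(contained)),
            "n_up": int((lfc > 0).sum()),
            "n_down": int((lfc < 0).sum())}


def annotate_results_regions(results: pd.DataFrame,
                             region_map: RegionMap) -> pd.Series:
    """Region annotation for each result row (gene/first_aa/last_aa columns)."""

    class _K:
        __slots__ = ("gene", "first_aa", "last_aa")

        def __init__(self, g, f, l):
            self.gene, self.first_aa, self.last_aa = g, f, l

    return pd.Series(
        [annotate_region(_K(r.gene, int(r.first_aa), int(r.last_aa)),
                         region_map)
         for r in results.itertuples(index=False)],
        index=results.index, name="region")
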
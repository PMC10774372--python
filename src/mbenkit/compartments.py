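"""Microdissected-bulk compartment analysis.

Differential expression between the nodular and internodular compartments
with patient fixed effects (limits: |log2FC| >= 0.5, BH-adjusted p <= 0.05),
single-sample rank-weighted signature enrichment, non-negative least squares
deconvolution of bulk profiles into cell-state proportions, and group
statistics on the recovered proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


def _squeeze_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes variance moderation (scaled inverse-chi-square prior).

    Fits the prior df ``d0`` and scale ``s0^2`` by matching moments of
    ``log(s2)`` against the theoretical chi-square log-moments, then returns
    the posterior variances ``(d0*s0^2 + df*s2) / (d0 + df)`` and ``d0``
    (``inf`` when the observed variances are as concentrated as the
    chi-square alone, i.e. fully pooled).
    """
    from scipy.special import digamma, polygamma

    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2)
    evar = max(np.var(e, ddof=1) - polygamma(1, df / 2.0), 0.0)
    if evar <= 1e-10:
        d0 = np.inf
        s0_2 = np.exp(np.mean(e) - digamma(df / 2.0) + np.log(df / 2.0))
        return np.full_like(s2, s0_2), d0
    # solve trigamma(d0/2) = evar for d0 by Newton iteration
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        tri = polygamma(1, x)
        delta = tri * (1.0 - tri / evar) / polygamma(2, x)
        x = max(x - delta, 1e-8)
        if abs(delta) < 1e-10:
            break
    d0 = 2.0 * x
    # prior scale from the mean of log s2 under the marginal F distribution
    s0_2 = np.exp(np.mean(e) - digamma(df / 2.0) + np.log(df / 2.0) + digamma(x) - np.log(x))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def de_between_compartments(
    bulk: pd.DataFrame,
    meta: pd.DataFrame,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
    moderate: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-gene linear model  expression ~ compartment + patient.

    ``bulk``: genes x samples, log2 scale.  ``meta``: per-sample ``patient``
    and ``compartment`` (nodular / internodular).  The compartment
    coefficient (nodular minus internodular) is the log2 fold change.
    With ``moderate`` (default) the per-gene residual variances are
    empirical-Bayes shrunken toward a common prior before the t-test, as is
    standard for small bulk designs.  Returns the full DEG table plus the
    significant gene sets split by sign.

    Raises if the design is confounded (compartment aliased by patient).
    """
    if not {"patient", "compartment"}.issubset(meta.columns):
        raise ValueError("meta needs 'patient' and 'compartment' columns")
    meta = meta.loc[bulk.columns]
    comp = (meta["compartment"] == "nodular").to_numpy(dtype=float)
    patients = pd.get_dummies(meta["patient"], drop_first=True).to_numpy(dtype=float)
    n_with_both = (
        meta.groupby("patient")["compartment"].nunique().ge(2).sum()
    )
    if n_with_both < 2:
        raise ValueError("need >= 2 patients with both compartments")

    X = np.column_stack([np.ones(len(comp)), comp, patients])
    X_null = np.column_stack([np.ones(len(comp)), patients])
    if np.linalg.matrix_rank(X) <= np.linalg.matrix_rank(X_null):
        raise ValueError("confounded design: compartment is aliased by patient")

    Y = bulk.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough samples for the model")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    t_df = df
    if moderate:
        sigma2, d0 = _squeeze_variances(sigma2, df)
        t_df = df + d0 if np.isfinite(d0) else 1e6
    se = np.sqrt(XtX_inv[1, 1] * sigma2)
    lfc = beta[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = np.where(se > 0, lfc / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), t_df)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": bulk.index,
            "log2fc": lfc,
            "t": tvals,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    table["significant"] = (table["qvalue"] <= alpha) & (table["log2fc"].abs() >= lfc_min)
    sig = table[table["significant"]]
    sets = {
        "nodular": sig.loc[sig["log2fc"] > 0, "gene"].tolist(),
        "internodular": sig.loc[sig["log2fc"] < 0, "gene"].tolist(),
    }
    return table.sort_values("pvalue", kind="stable").reset_index(drop=True), sets


def signature_enrichment(
    profiles: pd.DataFrame, gene_sets: dict[str, list[str]], tau: float = 0.25
) -> pd.DataFrame:
    """Single-sample rank-weighted KS enrichment (ssGSEA-style).

    Per sample, genes are ranked by descending expression; the running sum
    climbs by the normalized rank weight ``(N - pos + 1)**tau`` at set genes
    and falls by ``1/(N - n_set)`` elsewhere.  The score is the signed
    maximum deviation, so a set of top-ranked genes scores +1 at tau = 0.
    Returns a sets x samples score matrix.
    """
    genes = profiles.index.to_numpy()
    N = len(genes)
    scores = pd.DataFrame(0.0, index=list(gene_sets), columns=profiles.columns)
    for sample in profiles.columns:
        order = np.argsort(-profiles[sample].to_numpy(), kind="stable")
        ranked = genes[order]
        rank_weight = (N - np.arange(N)).astype(float) ** tau
        for name, gset in gene_sets.items():
            members = np.isin(ranked, list(gset))
            n_set = members.sum()
            if n_set == 0 or n_set == N:
                scores.loc[name, sample] = 0.0
                continue
            w = np.where(members, rank_weight, 0.0)
            hit = np.cumsum(w) / w.sum()
            miss = np.cumsum(~members) / (N - n_set)
            dev = hit - miss
            peak = np.argmax(np.abs(dev))
            scores.loc[name, sample] = dev[peak]
    return scores


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame     # samples x states, rows sum to 1
    residual_norm: pd.Series      # per-sample NNLS residual
    condition_number: float


def deconvolve_bulk(bulk: pd.DataFrame, state_signatures: pd.DataFrame) -> DeconvolutionResult:
    """Non-negative least squares deconvolution of bulk samples.

    Gene space is the intersection; both the bulk columns and the signature
    columns are normalized to unit sum (making the result invariant to a
    common rescaling of a sample), then per-sample NNLS proportions are
    renormalized to the simplex.
    """
    if state_signatures.shape[1] < 2:
        raise ValueError("need at least 2 states to deconvolve")
    shared = bulk.index.intersection(state_signatures.index)
    if len(shared) < state_signatures.shape[1]:
        raise ValueError("fewer shared genes than states")
    S = state_signatures.loc[shared].to_numpy(dtype=float)
    S = S / S.sum(axis=0, keepdims=True)
    cond = float(np.linalg.cond(S))
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn(
            f"signature matrix is rank deficient (condition number {cond:.3g})",
            stacklevel=2,
        )

    B = bulk.loc[shared].to_numpy(dtype=float)
    colsum = B.sum(axis=0, keepdims=True)
    if np.any(colsum <= 0):
        raise ValueError("bulk samples must have positive totals")
    B = B / colsum

    props = np.empty((bulk.shape[1], S.shape[1]))
    resid = np.empty(bulk.shape[1])
    for j in range(bulk.shape[1]):
        x, r = optimize.nnls(S, B[:, j])
        total = x.sum()
        props[j] = x / total if total > 0 else np.full(len(x), 1.0 / len(x))
        resid[j] = r
    return DeconvolutionResult(
        proportions=pd.DataFrame(props, index=bulk.columns, columns=state_signatures.columns),
        residual_norm=pd.Series(resid, index=bulk.columns, name="residual"),
        condition_number=cond,
    )


def composition_statistics(values: pd.DataFrame, covariate: pd.Series) -> pd.DataFrame:
    """Group or covariate tests on per-sample composition values.

    ``values``: samples x states (e.g. deconvolved proportions).  If
    ``covariate`` is categorical with two levels, a two-sided t-test per
    state; if numeric, Spearman correlation.  Degenerate (zero-variance
    identical) comparisons are reported as NA.
    """
    covariate = covariate.loc[values.index]
    numeric = pd.api.types.is_numeric_dtype(covariate)
    rows = []
    if numeric:
        for state in values.columns:
            v = values[state].to_numpy(dtype=float)
            if np.ptp(v) == 0 or np.ptp(covariate.to_numpy(dtype=float)) == 0:
                rows.append({"state": state, "statistic": np.nan, "pvalue": np.nan,
                             "method": "spearman"})
                continue
            rho, p = stats.spearmanr(v, covariate.to_numpy(dtype=float))
            rows.append({"state": state, "statistic": rho, "pvalue": p, "method": "spearman"})
    else:
        groups = covariate.unique()
        if len(groups) != 2:
            raise ValueError("categorical covariate must have exactly 2 levels")
        g1 = covariate == groups[0]
        for state in values.columns:
            a = values.loc[g1.to_numpy(), state].to_numpy(dtype=float)
            b = values.loc[(~g1).to_numpy(), state].to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                rows.append({"state": state, "statistic": np.nan, "pvalue": np.nan,
                             "method": "t-test"})
                continue
            t, p = stats.ttest_ind(a, b)
            rows.append({"state": state, "statistic": t, "pvalue": p, "method": "t-test"})
    return pd.DataFrame(rows)
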
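"""Two-sample Mendelian randomization under population structure.

Per-SNP association summaries (optionally PC-corrected), Wald-ratio and
fixed-effect inverse-variance-weighted estimators, and a replicated
experiment in which the exposure and outcome samples differ in size and in
how thoroughly each can detect — and hence correct for — shared ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .simulate import SimulationParams, make_cohort
from .structure import compute_pcs

__all__ = [
    "MREstimate",
    "WeakInstrumentError",
    "snp_summaries",
    "wald_ratio",
    "ivw",
    "n_detectable_pcs",
    "two_sample_experiment",
]

SUMMARY_COLUMNS = ["snp_index", "beta", "se", "n", "corrected", "k_pcs_used"]


class WeakInstrumentError(ValueError):
    pass


@dataclass
class MREstimate:
    method: str           # "wald" or "ivw"
    beta_iv: float
    se_iv: float
    n_snps_used: int


def snp_summaries(
    y: np.ndarray,
    X: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    snps: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-SNP OLS slope and SE for ``y ~ intercept + SNP (+ covariates)``.

    Implemented by residualizing both sides on the nuisance design
    (Frisch-Waugh), so all SNPs are handled in one vectorized pass.
    Monomorphic / collinear SNPs are dropped.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    snps = np.arange(X.shape[1]) if snps is None else np.asarray(snps, dtype=int)
    if snps.size == 0:
        raise ValueError("snps must be non-empty")
    if covariates is None:
        A = np.ones((n, 1))
        k_pcs = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        A = np.column_stack([np.ones(n), C])
        k_pcs = C.shape[1]
    p = A.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > {p + 2} observations")
    coef_y, *_ = np.linalg.lstsq(A, y, rcond=None)
    ry = y - A @ coef_y
    G = X[:, snps]
    coef_g, *_ = np.linalg.lstsq(A, G, rcond=None)
    rg = G - A @ coef_g
    ss = np.einsum("ij,ij->j", rg, rg)
    usable = ss > 1e-10 * n
    df = n - p - 1
    rows = []
    for j, snp in enumerate(snps):
        if not usable[j]:
            continue
        beta = float(rg[:, j] @ ry / ss[j])
        rss = float(ry @ ry) - beta * beta * ss[j]
        se = float(np.sqrt(max(rss, 0.0) / df / ss[j]))
        rows.append(
            {
                "snp_index": int(snp),
                "beta": beta,
                "se": se,
                "n": n,
                "corrected": k_pcs > 0,
                "k_pcs_used": k_pcs,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def wald_ratio(exposure, outcome, weak_z: float = 3.0) -> MREstimate:
    """Single-SNP IV estimate: outcome slope over exposure slope, with a
    first-order delta-method standard error."""
    if int(exposure["snp_index"]) != int(outcome["snp_index"]):
        raise ValueError("exposure and outcome summaries refer to different SNPs")
    be, se_e = float(exposure["beta"]), float(exposure["se"])
    bo, se_o = float(outcome["beta"]), float(outcome["se"])
    if se_e <= 0 or se_o <= 0:
        raise ValueError("standard errors must be positive")
    if abs(be) / se_e < weak_z:
        raise WeakInstrumentError(
            f"exposure |z| = {abs(be) / se_e:.2f} below threshold {weak_z}"
        )
    beta_iv = bo / be
    se_iv = np.sqrt(se_o**2 / be**2 + bo**2 * se_e**2 / be**4)
    return MREstimate(method="wald", beta_iv=float(beta_iv), se_iv=float(se_iv), n_snps_used=1)


def ivw(
    exposures: pd.DataFrame, outcomes: pd.DataFrame, weak_z: float = 3.0
) -> MREstimate:
    """Fixed-effect inverse-variance-weighted average of per-SNP Wald ratios.

    SNPs failing the weak-instrument guard are dropped; with a single SNP the
    result is identical to :func:`wald_ratio`.
    """
    merged = exposures.merge(
        outcomes, on="snp_index", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise ValueError("no SNPs shared between exposure and outcome summaries")
    ratios, variances = [], []
    for _, row in merged.iterrows():
        try:
            est = wald_ratio(
                {"snp_index": row["snp_index"], "beta": row["beta_exp"], "se": row["se_exp"]},
                {"snp_index": row["snp_index"], "beta": row["beta_out"], "se": row["se_out"]},
                weak_z=weak_z,
            )
        except WeakInstrumentError:
            continue
        ratios.append(est.beta_iv)
        variances.append(est.se_iv**2)
    if not ratios:
        raise WeakInstrumentError("no instrument passed the weak-instrument guard")
    if len(ratios) == 1:  # exact Wald identity, no sqrt round-trip
        return MREstimate(
            method="ivw", beta_iv=ratios[0], se_iv=float(np.sqrt(variances[0])),
            n_snps_used=1,
        )
    w = 1.0 / np.asarray(variances)
    beta = float(np.sum(w * np.asarray(ratios)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MREstimate(method="ivw", beta_iv=beta, se_iv=se, n_snps_used=len(ratios))


def n_detectable_pcs(X: np.ndarray, k_max: int = 20, edge_factor: float = 1.0) -> int:
    """Number of leading PCs whose eigenvalue clears the bulk-spectrum edge.

    Eigenvalues of the standardized-genotype correlation matrix are compared
    with the Marchenko-Pastur upper edge ``(1 + sqrt(L/n))^2`` — the
    phase-transition threshold below which a structure axis is statistically
    invisible at this sample size.
    """
    X = np.asarray(X, dtype=float)
    n, L = X.shape
    sd = X.std(axis=0, ddof=1)
    kept = sd > 0
    Z = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
    k = min(k_max, n - 1, int(kept.sum()))
    _, S, _ = randomized_svd(Z, n_components=k, n_iter=7, random_state=0)
    eigs = S**2 / (n - 1)
    edge = edge_factor * (1.0 + np.sqrt(kept.sum() / n)) ** 2
    return int(np.sum(eigs > edge))


def _sample_scores(X: np.ndarray, k: int) -> Optional[np.ndarray]:
    if k <= 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # monomorphic drops expected
        return compute_pcs(X, k=k).scores


def two_sample_experiment(
    params: SimulationParams,
    n_exposure: int,
    n_outcome: int,
    gamma: float = 0.5,
    delta: float = 0.0,
    pc_rule: str = "fixed_k",
    k_pcs: int = 20,
    n_replicates: int = 20,
    seed: Optional[int] = None,
    weak_z: float = 3.0,
    arms: Sequence[str] = ("uncorrected", "full", "differential"),
) -> pd.DataFrame:
    """Bias of two-sample IVW estimates under differential structure correction.

    Each replicate simulates one structured population, splits it into
    disjoint exposure (size ``n_exposure``) and outcome (size ``n_outcome``)
    samples, builds the outcome as ``O = gamma*T + delta*A_std + noise``
    (``A_std`` the standardized admixture fraction — a direct ancestry →
    outcome path), and estimates ``gamma`` by IVW using the causal SNPs as
    instruments.  Arms:

    - ``uncorrected``: no PC covariates in either sample;
    - ``full``: ``k_pcs`` PCs in both samples;
    - ``differential``: per-sample PC count chosen by ``pc_rule``
      (``"detect"`` keeps only eigenvalue-detectable components, so the
      smaller sample typically keeps fewer; ``"fixed_k"`` uses ``k_pcs`` in
      the larger sample and none in the smaller).
    """
    if n_exposure < 50 or n_outcome < 50:
        raise ValueError("n_exposure and n_outcome must be >= 50")
    if pc_rule not in ("fixed_k", "detect"):
        raise ValueError("pc_rule must be 'fixed_k' or 'detect'")
    n_total = n_exposure + n_outcome
    master = params.seed if seed is None else seed
    rep_seeds = np.random.SeedSequence(master).generate_state(n_replicates)
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        p_rep = params.with_overrides(seed=int(rep_seed), n_individuals=n_total)
        cohort = make_cohort(p_rep)
        rng = np.random.default_rng(np.random.SeedSequence([int(rep_seed), 13]))
        T = cohort.phenotype
        O = gamma * T + delta * cohort.environment + rng.standard_normal(n_total)
        idx = rng.permutation(n_total)
        i_exp, i_out = idx[:n_exposure], idx[n_exposure:]
        X_exp, X_out = cohort.genotypes[i_exp], cohort.genotypes[i_out]
        instruments = cohort.arch.causal_index

        k_cache: dict[int, int] = {}

        def detected_k(X: np.ndarray) -> int:
            key = id(X)
            if key not in k_cache:
                k_cache[key] = min(k_pcs, n_detectable_pcs(X, k_max=k_pcs))
            return k_cache[key]

        for arm in arms:
            if arm == "uncorrected":
                k_exp = k_out = 0
            elif arm == "full":
                k_exp = k_out = k_pcs
            elif arm == "differential":
                if pc_rule == "detect":
                    k_exp, k_out = detected_k(X_exp), detected_k(X_out)
                else:
                    big_is_exp = n_exposure >= n_outcome
                    k_exp = k_pcs if big_is_exp else 0
                    k_out = 0 if big_is_exp else k_pcs
            else:
                raise ValueError(f"unknown arm {arm!r}")
            try:
                exp_sum = snp_summaries(
                    T[i_exp], X_exp, _sample_scores(X_exp, k_exp), instruments
                )
                out_sum = snp_summaries(
                    O[i_out], X_out, _sample_scores(X_out, k_out), instruments
                )
                est = ivw(exp_sum, out_sum, weak_z=weak_z)
                beta_iv, se_iv, n_used = est.beta_iv, est.se_iv, est.n_snps_used
            except (WeakInstrumentError, ValueError):
                beta_iv = se_iv = np.nan
                n_used = 0
            rows.append(
                {
                    "replicate": rep,
                    "arm": arm,
                    "k_exposure": k_exp,
                    "k_outcome": k_out,
                    "n_snps_used": n_used,
                    "beta_iv": beta_iv,
                    "se_iv": se_iv,
                    "bias": beta_iv - gamma,
                }
            )
    return pd.DataFrame(rows)
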
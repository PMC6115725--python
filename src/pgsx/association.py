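"""Single-SNP association: whole-cohort and BMI-stratified GWAS.

Per-SNP models are ordinary least squares of the phenotype on covariates
plus additive dosage.  The genome-wide scan uses the Frisch–Waugh–Lovell
residualization identity to share the covariate projection across SNPs,
which is algebraically identical to fitting each full model separately.
P-values come from the t reference distribution with exact residual
degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PC_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex"] + PC_COLUMNS


@dataclasses.dataclass
class AssocResult:
    """Per-SNP association record. ``beta`` is NaN when undefined."""

    snp_id: str
    beta: float
    se: float
    t: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.beta)


@dataclasses.dataclass(frozen=True)
class StratumDefinition:
    """A BMI interval with explicit bound closure, e.g. [20, 25)."""

    label: str
    lower: float
    upper: float
    lower_closed: bool = True
    upper_closed: bool = False

    def contains(self, bmi: np.ndarray) -> np.ndarray:
        bmi = np.asarray(bmi)
        lo = bmi >= self.lower if self.lower_closed else bmi > self.lower
        hi = bmi <= self.upper if self.upper_closed else bmi < self.upper
        return lo & hi


def default_strata() -> list[StratumDefinition]:
    """WHO-style BMI categories as half-open intervals partitioning (0, inf).

    Underweight (0, 20), normoweight [20, 25), overweight [25, 30),
    obese [30, inf).  Half-open from the left guarantees every BMI value
    lands in exactly one stratum.
    """
    return [
        StratumDefinition("underweight", 0.0, 20.0, lower_closed=False),
        StratumDefinition("normoweight", 20.0, 25.0),
        StratumDefinition("overweight", 25.0, 30.0),
        StratumDefinition("obese", 30.0, math.inf),
    ]


def _design(pheno: pd.DataFrame, covar_names: Sequence[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(pheno))] + [pheno[c].to_numpy(dtype=float) for c in covar_names]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    return X


def mean_impute(g: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the observed per-SNP mean."""
    g = np.asarray(g, dtype=float)
    if np.isnan(g).any():
        g = np.where(np.isnan(g), np.nanmean(g), g)
    return g


def fit_snp(g: np.ndarray, y: np.ndarray, X: np.ndarray,
            snp_id: str = "") -> AssocResult:
    """OLS of ``y`` on ``[X, g]``; returns the dosage coefficient.

    ``X`` must include the intercept.  Missing dosages are mean-imputed; a
    dosage vector constant after imputation yields a flagged (NaN) result
    rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    X = np.asarray(X, dtype=float)
    rank_X = np.linalg.matrix_rank(X)
    if rank_X < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    g = mean_impute(g)
    n = len(y)

    if np.ptp(g) == 0:
        return AssocResult(snp_id, math.nan, math.nan, math.nan, math.nan, n)

    design = np.column_stack([X, g])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - rank_X - 1
    if df <= 0:
        return AssocResult(snp_id, math.nan, math.nan, math.nan, math.nan, n)
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(design.T @ design)
    se = math.sqrt(sigma2 * XtX_inv[-1, -1])
    beta = coef[-1]
    if se == 0:
        t = math.inf if beta != 0 else 0.0
        p = np.nextafter(0, 1) if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2 * stats.t.sf(abs(t), df)
    return AssocResult(snp_id, beta, se, t, max(p, np.nextafter(0, 1)), n)


def run_gwas(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    covar_names: Sequence[str] = DEFAULT_COVARIATES,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    phenotype: str = "bmi",
) -> pd.DataFrame:
    """Per-SNP additive GWAS; returns a summary-statistics table.

    The effect allele is allele 1 of each SNP.  SNPs failing the MAF or
    missingness filter within the analysis sample are dropped.  Results are
    identical to calling :func:`fit_snp` SNP by SNP.
    """
    pheno = pheno.set_index("sample_id").loc[G.samples].reset_index()
    y = pheno[phenotype].to_numpy(dtype=float)
    X = _design(pheno, covar_names)
    n, m = G.dosages.shape

    miss = np.isnan(G.dosages).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G.dosages, axis=0) / 2
    maf = np.minimum(freq, 1 - freq)
    keep = (maf >= maf_min) & (miss <= miss_max) & ~np.isnan(freq)
    if not keep.any():
        raise ValueError("no SNPs pass MAF/missingness filters")

    D = G.dosages[:, keep].copy()
    col_means = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_means, np.where(nan_mask)[1])

    # Frisch-Waugh: residualize y and every dosage column on the covariates
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    D_r = D - Q @ (Q.T @ D)

    gg = np.einsum("ij,ij->j", D_r, D_r)
    gy = D_r.T @ y_r
    df = n - X.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = y_r @ y_r - beta**2 * gg
        se = np.sqrt(np.maximum(rss, 0) / df / gg)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    out = G.snps.loc[keep, ["id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    out = out.rename(columns={"a1": "effect_allele", "a2": "other_allele"})
    out["freq"] = freq[keep]
    out["n"] = n
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    return out


def stratified_gwas(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    covar_names: Sequence[str] = DEFAULT_COVARIATES,
    strata: Sequence[StratumDefinition] | None = None,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run the GWAS separately within each BMI stratum.

    Strata with fewer samples than covariates + 2 are skipped with a
    warning.  Assignment uses raw BMI.
    """
    if strata is None:
        strata = default_strata()
    pheno = pheno.set_index("sample_id").loc[G.samples].reset_index()
    bmi = pheno["bmi"].to_numpy(dtype=float)

    results: dict[str, pd.DataFrame] = {}
    for stratum in strata:
        mask = stratum.contains(bmi)
        n_s = int(mask.sum())
        if n_s < len(covar_names) + 2:
            logger.warning("stratum %s has %d samples; skipped", stratum.label, n_s)
            continue
        results[stratum.label] = run_gwas(
            G.subset_samples(mask), pheno[mask], covar_names,
            maf_min=maf_min, miss_max=miss_max,
        )
        logger.info("stratum %s: n = %d", stratum.label, n_s)
    return results


def replication_summary(
    own: pd.DataFrame,
    reference_ids: Sequence[str],
    alphas: Sequence[float] = (0.05, 1e-5),
) -> pd.DataFrame:
    """Count reference SNPs replicating in our results at each threshold.

    The expected count under the null is (number of reference SNPs tested)
    x alpha.  Reference SNPs absent from our results are reported but do
    not enter the counts.
    """
    own_idx = own.set_index("id")
    present = [s for s in reference_ids if s in own_idx.index]
    missing = [s for s in reference_ids if s not in own_idx.index]
    if missing:
        logger.warning("%d reference SNPs absent from own stats", len(missing))
    pvals = own_idx.loc[present, "p"].to_numpy()
    m_ref = len(present)

    rows = []
    for alpha in alphas:
        observed = int((pvals < alpha).sum()) if alpha < 1 else m_ref
        rows.append({
            "alpha": alpha,
            "n_tested": m_ref,
            "n_missing": len(missing),
            "observed": observed,
            "expected": m_ref * alpha,
            "percent": 100.0 * observed / m_ref if m_ref else math.nan,
        })
    return pd.DataFrame(rows)


def qq_points(pvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot.

    Expected quantile i of m is (i - 0.5)/m; both axes returned with the
    smallest p (largest -log10) last.
    """
    p = np.sort(np.asarray(pvals, dtype=float))[::-1]
    m = len(p)
    if m == 0:
        raise ValueError("no p-values")
    expected = -np.log10((np.arange(m, 0, -1) - 0.5) / m)
    observed = -np.log10(p)
    return expected, observed


def beta_concordance(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    snp_ids: Sequence[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of effect sizes after effect-allele alignment.

    Betas in ``stats_b`` are sign-flipped where its effect/other alleles are
    swapped relative to ``stats_a``; SNPs whose allele pairs do not match
    either way are dropped.
    """
    a = stats_a.set_index("id")
    b = stats_b.set_index("id")
    common = a.index.intersection(b.index)
    if snp_ids is not None:
        common = common.intersection(pd.Index(snp_ids))
    pairs = []
    for snp in common:
        ea_a, oa_a = a.at[snp, "effect_allele"], a.at[snp, "other_allele"]
        ea_b, oa_b = b.at[snp, "effect_allele"], b.at[snp, "other_allele"]
        beta_b = b.at[snp, "beta"]
        if (ea_a, oa_a) == (ea_b, oa_b):
            pass
        elif (ea_a, oa_a) == (oa_b, ea_b):
            beta_b = -beta_b
        else:
            logger.warning("allele mismatch at %s; dropped", snp)
            continue
        pairs.append({"id": snp, "beta_a": a.at[snp, "beta"], "beta_b": beta_b})
    aligned = pd.DataFrame(pairs)
    if len(aligned) < 3:
        raise ValueError("fewer than 3 aligned SNPs")
    r, p = stats.pearsonr(aligned["beta_a"], aligned["beta_b"])
    return float(r), float(p), aligned
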
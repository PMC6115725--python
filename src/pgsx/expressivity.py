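"""Allele expressivity: per-SNP effects across deciles of polygenic background.

For each SNP, BMI is regressed on dosage within each decile of an
unweighted background polygenic score built from the same SNP panel
(simple regression, no covariates).  Regressing the ten decile-wise
estimates on decile index gives the SNP's *expressivity slope*: positive
when the allele's effect grows with the polygenic background.  Cohort-level
evidence for background amplification is the exact two-sided binomial sign
test on the count of positive slopes against a null proportion of one
half, and the Pearson correlation of slopes with external effect sizes.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix
from .association import mean_impute
from .pgs_builder import PGSDefinition, assign_deciles, compute_score

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ExpressivityResult:
    """Per-SNP slopes and the cohort-level sign-test summary.

    ``per_snp`` columns: id, slope, slope_se, beta_1..beta_10, se_1..se_10,
    n_defined_deciles.  ``n`` counts SNPs entering the sign test, ``k`` the
    positive slopes among them.
    """

    per_snp: pd.DataFrame
    n: int
    k: int
    p_binomial: float
    subset: dict | None = None

    @property
    def fraction_positive(self) -> float:
        return self.k / self.n if self.n else math.nan


def _simple_ols(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and SE of y on g with intercept; (NaN, NaN) if g is constant."""
    if np.ptp(g) == 0 or len(g) < 3:
        return math.nan, math.nan
    gc = g - g.mean()
    sxx = gc @ gc
    beta = (gc @ y) / sxx
    resid = y - y.mean() - beta * gc
    sigma2 = resid @ resid / (len(g) - 2)
    return float(beta), float(math.sqrt(sigma2 / sxx))


def snp_decile_betas(
    g: np.ndarray,
    bmi: np.ndarray,
    deciles: np.ndarray,
    covars: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-decile effect of one SNP: OLS of BMI on dosage per decile.

    The default model is BMI ~ SNP with no covariates; pass ``covars`` for
    a sensitivity analysis with adjustment.  Deciles where the SNP is
    monomorphic get NaN.
    """
    g = mean_impute(g)
    betas = np.full(10, np.nan)
    ses = np.full(10, np.nan)
    for d in range(1, 11):
        mask = deciles == d
        if covars is None:
            betas[d - 1], ses[d - 1] = _simple_ols(g[mask], bmi[mask])
        else:
            X = np.column_stack([np.ones(mask.sum()), g[mask], covars[mask]])
            if np.ptp(g[mask]) == 0 or np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            coef, _, _, _ = np.linalg.lstsq(X, bmi[mask], rcond=None)
            resid = bmi[mask] - X @ coef
            df = mask.sum() - X.shape[1]
            if df <= 0:
                continue
            cov = np.linalg.inv(X.T @ X) * (resid @ resid / df)
            betas[d - 1] = coef[1]
            ses[d - 1] = math.sqrt(cov[1, 1])
    return betas, ses


def expressivity_slope(decile_betas: np.ndarray) -> tuple[float, float]:
    """Unweighted OLS of the defined decile betas on decile index 1..10."""
    b = np.asarray(decile_betas, dtype=float)
    idx = np.arange(1, 11, dtype=float)
    ok = np.isfinite(b)
    if ok.sum() < 3:
        return math.nan, math.nan
    return _simple_ols(idx[ok], b[ok])


def binomial_sign_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p by pmf enumeration.

    Sums Binomial(n, p0) point probabilities of every outcome no more
    probable than the observed one (the R ``binom.test`` convention); at
    p0 = 0.5 this equals the doubled smaller tail, capped at 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative tolerance matches R's: outcomes within (1 + 1e-7) x pmf(k)
    p = float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())
    return min(p, 1.0)


def cohort_expressivity(
    G: GenotypeMatrix,
    snp_ids: Sequence[str],
    pheno: pd.DataFrame,
    maf_min: float = 0.05,
    background: str = "include",
    subset_ids: Sequence[str] | None = None,
    max_undefined: int = 3,
    effect_alleles: dict[str, str] | None = None,
) -> ExpressivityResult:
    """Full expressivity analysis over a SNP panel.

    SNPs with within-cohort MAF below ``maf_min`` are removed; the
    background score is the unweighted count of trait-increasing alleles
    over the surviving panel (``effect_alleles`` maps SNP id -> increasing
    allele; default counts allele 1).  With ``background="loo"`` each focal
    SNP is excluded from its own background score before decile assignment
    (guards against self-inclusion inflating within-decile dosage
    variance).  SNPs with more than ``max_undefined`` undefined decile
    betas are excluded from slope fitting.  ``subset_ids`` triggers an
    additional sign test restricted to that subset.
    """
    if background not in ("include", "loo"):
        raise ValueError("background must be 'include' or 'loo'")
    pheno = pheno.set_index("sample_id").loc[G.samples].reset_index()
    bmi = pheno["bmi"].to_numpy(dtype=float)

    lookup = {s: j for j, s in enumerate(G.snps["id"])}
    panel = [s for s in snp_ids if s in lookup]
    if len(panel) < len(snp_ids):
        logger.warning("%d panel SNPs absent from genotypes",
                       len(snp_ids) - len(panel))

    doses = {}
    kept = []
    for s in panel:
        g = mean_impute(G.dosages[:, lookup[s]])
        if effect_alleles is not None:
            ea = effect_alleles.get(s)
            a1 = G.snps.at[lookup[s], "a1"]
            a2 = G.snps.at[lookup[s], "a2"]
            if ea == a2:
                g = 2.0 - g
            elif ea not in (a1, None):
                logger.warning("effect allele mismatch at %s; skipped", s)
                continue
        f = g.mean() / 2
        if min(f, 1 - f) < maf_min:
            continue
        doses[s] = g
        kept.append(s)
    if not kept:
        raise ValueError("no SNPs survive the MAF filter")
    logger.info("expressivity panel: %d of %d SNPs after MAF >= %g filter",
                len(kept), len(panel), maf_min)

    D = np.column_stack([doses[s] for s in kept])
    total = D.sum(axis=1)
    deciles_all = assign_deciles(total)

    rows = []
    for col, s in enumerate(kept):
        if background == "loo":
            deciles = assign_deciles(total - D[:, col])
        else:
            deciles = deciles_all
        betas, ses = snp_decile_betas(D[:, col], bmi, deciles)
        n_undef = int(np.isnan(betas).sum())
        if n_undef > max_undefined:
            logger.warning("%s: %d undefined decile betas; excluded", s, n_undef)
            slope, slope_se = math.nan, math.nan
        else:
            slope, slope_se = expressivity_slope(betas)
        row = {"id": s, "slope": slope, "slope_se": slope_se,
               "n_defined_deciles": 10 - n_undef}
        row.update({f"beta_{d}": betas[d - 1] for d in range(1, 11)})
        row.update({f"se_{d}": ses[d - 1] for d in range(1, 11)})
        rows.append(row)
    per_snp = pd.DataFrame(rows)

    tested = per_snp.dropna(subset=["slope"])
    n = len(tested)
    k = int((tested["slope"] > 0).sum())
    p = binomial_sign_test(k, n) if n else math.nan
    result = ExpressivityResult(per_snp=per_snp, n=n, k=k, p_binomial=p)

    if subset_ids is not None:
        sub = tested[tested["id"].isin(set(subset_ids))]
        n_s = len(sub)
        k_s = int((sub["slope"] > 0).sum())
        result.subset = {
            "n": n_s, "k": k_s,
            "p_binomial": binomial_sign_test(k_s, n_s) if n_s else math.nan,
        }
    return result


def slope_effect_correlation(
    slopes: np.ndarray, reference_betas: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of expressivity slopes with external betas.

    Both arrays must be oriented to the same effect allele; NaN pairs are
    dropped.
    """
    s = np.asarray(slopes, dtype=float)
    b = np.asarray(reference_betas, dtype=float)
    ok = np.isfinite(s) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    r, p = stats.pearsonr(s[ok], b[ok])
    return float(r), float(p)
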
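"""Polygenic-score construction: p-value binning, LD pruning, proxy removal,
scoring, and the orthogonalizing residualization cascade.

A score is defined by a SNP list with an effect allele and a weight
(weight 1 for unweighted allele-count scores).  Candidate SNPs are first
partitioned into summary p-value bins, cleaned of proxies of the anchor set
(the genome-wide hits that form the strongest score), and LD-pruned within
sliding windows so that no surviving pair exceeds the r² ceiling.  The
residualization cascade then replaces each weaker-bin score by its OLS
residuals on all stronger-bin scores, leaving mutually uncorrelated
predictors so each bin's decile profile reflects its independent signal.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .association import mean_impute

logger = logging.getLogger(__name__)

#: the p-value bins used for the score ladder, strongest first:
#: (label, lower, upper] on the summary p scale
DEFAULT_BINS = [
    ("p1e7_1e5", 1e-7, 1e-5),
    ("p1e5_1e3", 1e-5, 1e-3),
    ("p1e3_0.01", 1e-3, 0.01),
    ("p0.01_0.05", 0.01, 0.05),
    ("null_p0.95", 0.95, 1.0),
]


@dataclasses.dataclass
class PGSDefinition:
    """A named SNP set with orientation and weights.

    ``table`` has columns ``id``, ``effect_allele``, ``weight``; unweighted
    scores carry weight 1 and orient the effect allele to the
    trait-increasing allele of the summary statistics.
    """

    name: str
    table: pd.DataFrame
    p_bin: tuple[float, float] | None = None
    pruned_by: str | None = None
    proxies_removed_against: str | None = None

    @property
    def n_snps(self) -> int:
        return len(self.table)


def ld_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairs with a missing value in either vector are dropped; a constant
    vector yields NaN (undefined), not an error.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    ok = ~np.isnan(g_a) & ~np.isnan(g_b)
    a, b = g_a[ok], g_b[ok]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(D: np.ndarray) -> np.ndarray:
    """r² matrix for a (n x k) mean-imputed dosage block; NaN on constants."""
    sd = D.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(D, rowvar=False)
    C = np.atleast_2d(C)
    R2 = C * C
    R2[sd == 0, :] = np.nan
    R2[:, sd == 0] = np.nan
    return R2


def ld_prune(
    G: GenotypeMatrix,
    candidate_ids: Sequence[str],
    window: float = 10_000,
    step: int = 5,
    r2_max: float = 0.5,
    priority: Mapping[str, float] | None = None,
    window_units: str = "kb",
) -> list[str]:
    """Greedy sliding-window LD pruning.

    Within each window (``window`` base pairs when ``window_units="kb"``
    style distances are given in bp, or ``window`` SNPs when
    ``window_units="snps"``), while any surviving pair has r² > ``r2_max``
    the lower-priority member is removed.  Priority is the summary
    -log10 p (``priority`` maps SNP id -> -log10 p); ties are broken by
    removing the SNP at the later position.  The window slides ``step``
    SNPs at a time, so no surviving pair within any window exceeds the
    ceiling.  SNPs must be position-sorted within chromosome.
    """
    if window_units not in ("kb", "snps"):
        raise ValueError("window_units must be 'kb' or 'snps'")
    lookup = {s: j for j, s in enumerate(G.snps["id"])}
    cand = [s for s in candidate_ids if s in lookup]
    if len(cand) < len(candidate_ids):
        logger.warning(
            "%d candidate SNPs absent from genotypes", len(candidate_ids) - len(cand)
        )
    meta = G.snps.set_index("id").loc[cand]
    for chrom, grp in meta.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"candidate SNPs not position-sorted on chrom {chrom}")

    prio = priority or {}
    removed: set[str] = set()

    for chrom, grp in meta.groupby("chrom", sort=False):
        ids = list(grp.index)
        pos = grp["pos"].to_numpy()
        start = 0
        while start < len(ids):
            if window_units == "snps":
                end = min(start + int(window), len(ids))
            else:
                end = start
                while end < len(ids) and pos[end] - pos[start] < window:
                    end += 1
            win = [s for s in ids[start:end] if s not in removed]
            if len(win) > 1:
                cols = [lookup[s] for s in win]
                D = np.column_stack([mean_impute(G.dosages[:, c]) for c in cols])
                R2 = _pairwise_r2(D)
                alive = list(range(len(win)))
                while True:
                    worst = None
                    for ii in range(len(alive)):
                        for jj in range(ii + 1, len(alive)):
                            r2 = R2[alive[ii], alive[jj]]
                            if np.isfinite(r2) and r2 > r2_max:
                                worst = (alive[ii], alive[jj])
                                break
                        if worst:
                            break
                    if worst is None:
                        break
                    i, j = worst
                    pi = prio.get(win[i], 0.0)
                    pj = prio.get(win[j], 0.0)
                    # victim: weaker summary association; tie -> later position
                    victim = j if (pj < pi or (pj == pi)) else i
                    removed.add(win[victim])
                    alive.remove(victim)
            if end >= len(ids):
                break
            start += step

    return [s for s in cand if s not in removed]


def remove_proxies(
    candidate_ids: Sequence[str],
    anchor_ids: Sequence[str],
    G: GenotypeMatrix,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Drop candidates in LD (r² > threshold) with any anchor SNP.

    Anchors absent from the genotype panel are skipped with a warning.
    A candidate that *is* an anchor is removed (r² = 1 with itself).
    """
    lookup = {s: j for j, s in enumerate(G.snps["id"])}
    anchors = [a for a in anchor_ids if a in lookup]
    if len(anchors) < len(anchor_ids):
        logger.warning(
            "%d anchor SNPs absent from genotypes", len(anchor_ids) - len(anchors)
        )
    if not anchors:
        return list(candidate_ids)
    A = np.column_stack([mean_impute(G.dosages[:, lookup[a]]) for a in anchors])

    kept = []
    for snp in candidate_ids:
        if snp not in lookup:
            kept.append(snp)
            continue
        g = mean_impute(G.dosages[:, lookup[snp]])
        r2s = np.array([ld_r2(g, A[:, k]) for k in range(A.shape[1])])
        if np.nanmax(r2s, initial=0.0) <= r2_threshold:
            kept.append(snp)
    return kept


def partition_by_pvalue(
    stats: pd.DataFrame,
    bins: Sequence[tuple[str, float, float]] = tuple(DEFAULT_BINS),
) -> dict[str, list[str]]:
    """Assign SNPs to half-open p-value bins (lower, upper].

    The control bin spanning [0.95, 1] is closed on both ends so p = 0.95
    and p = 1 both land there.  Each SNP falls in at most one bin.
    """
    out: dict[str, list[str]] = {}
    for label, lo, hi in bins:
        if hi >= 1.0:
            mask = (stats["p"] >= lo) & (stats["p"] <= hi)
        else:
            mask = (stats["p"] > lo) & (stats["p"] <= hi)
        out[label] = stats.loc[mask, "id"].tolist()
    return out


def make_definition(
    name: str,
    stats: pd.DataFrame,
    snp_ids: Sequence[str],
    weighted: bool = False,
    p_bin: tuple[float, float] | None = None,
) -> PGSDefinition:
    """Build a score definition from summary statistics.

    Orientation: the effect allele is the trait-increasing allele (summary
    beta oriented positive), so unweighted scores count BMI-increasing
    alleles and weighted scores carry non-negative weights.
    """
    sub = stats.set_index("id").loc[list(snp_ids)].reset_index()
    flip = sub["beta"] < 0
    ea = np.where(flip, sub["other_allele"], sub["effect_allele"])
    weight = np.abs(sub["beta"]) if weighted else np.ones(len(sub))
    table = pd.DataFrame({"id": sub["id"], "effect_allele": ea, "weight": weight})
    return PGSDefinition(name=name, table=table, p_bin=p_bin)


def compute_score(
    G: GenotypeMatrix,
    pgs_def: PGSDefinition,
    allow_strand_flip: bool = False,
) -> pd.DataFrame:
    """Per-sample score: sum over SNPs of weight x dosage of effect allele.

    Dosages are oriented to the effect allele (2 - dosage when the effect
    allele is allele 2); missing dosages are mean-imputed.  SNPs absent from
    the genotypes, or with an allele pair that matches neither directly nor
    swapped, are skipped with a count.  Returns columns ``sample_id``,
    ``score``, ``n_snps_used``.
    """
    lookup = {s: j for j, s in enumerate(G.snps["id"])}
    score = np.zeros(G.n_samples)
    used = 0
    skipped_absent = 0
    skipped_mismatch = 0
    comp = str.maketrans("ACGT", "TGCA")
    for row in pgs_def.table.itertuples(index=False):
        j = lookup.get(row.id)
        if j is None:
            skipped_absent += 1
            continue
        a1, a2 = G.snps.at[j, "a1"], G.snps.at[j, "a2"]
        ea = row.effect_allele
        if allow_strand_flip and ea not in (a1, a2):
            ea_f = ea.translate(comp)
            if ea_f in (a1, a2):
                ea = ea_f
        if ea == a1:
            dose = mean_impute(G.dosages[:, j])
        elif ea == a2:
            dose = 2.0 - mean_impute(G.dosages[:, j])
        else:
            logger.warning("allele mismatch for %s (%s vs %s/%s); skipped",
                           row.id, ea, a1, a2)
            skipped_mismatch += 1
            continue
        score += row.weight * dose
        used += 1
    if used == 0:
        raise ValueError("no usable SNPs for score " + pgs_def.name)
    if skipped_absent or skipped_mismatch:
        logger.info("score %s: %d SNPs used, %d absent, %d mismatched",
                    pgs_def.name, used, skipped_absent, skipped_mismatch)
    return pd.DataFrame(
        {"sample_id": G.samples, "score": score, "n_snps_used": used}
    )


def residualize_cascade(scores: pd.DataFrame) -> pd.DataFrame:
    """Orthogonalize a score matrix strongest-to-weakest.

    ``scores``: one column per score level, ordered strongest bin first,
    identical samples per row.  Level 1 passes through unchanged; level k
    is replaced by its OLS residuals on intercept + the *original* levels
    1..k-1 (the span equals that of the residualized ones, so sequential
    and joint regression agree).  Output columns are pairwise uncorrelated
    to numerical tolerance.
    """
    M = scores.to_numpy(dtype=float)
    n, k = M.shape
    out = np.empty_like(M)
    out[:, 0] = M[:, 0]
    for level in range(1, k):
        X = np.column_stack([np.ones(n), M[:, :level]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            C = np.corrcoef(M[:, :level], rowvar=False)
            C = np.atleast_2d(C)
            ii, jj = np.unravel_index(
                np.argmax(np.abs(C - np.eye(level))), C.shape)
            raise ValueError(
                f"collinear scores: {scores.columns[ii]!r} and "
                f"{scores.columns[jj]!r}"
            )
        coef, _, _, _ = np.linalg.lstsq(X, M[:, level], rcond=None)
        out[:, level] = M[:, level] - X @ coef
    return pd.DataFrame(out, columns=scores.columns, index=scores.index)


def assign_deciles(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-count decile assignment (1..10), ties broken by stable order.

    Bin sizes differ by at most one sample.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    for d in range(n_bins):
        bins[order[edges[d]:edges[d + 1]]] = d + 1
    return bins
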
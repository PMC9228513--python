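"""Differential methylation between two groups of NB-distributed tag counts.

Model
-----
Tag counts at site *s* in sample *j* of group *g* are modelled as negative
binomial, ``y_sj ~ NB(mean = N_j * p_sg, dispersion = phi)``: ``N_j`` is
the library size and ``phi`` the common biological dispersion
(variance = mu + phi * mu^2).  Inference follows the classic
quantile-adjusted conditional maximum likelihood (qCML) recipe for small
two-group designs:

1. *equalize libraries*: map every sample's counts onto a common library
   size (the geometric mean) by quantile mapping between NB distributions
   at the current dispersion, alternated with dispersion estimation until
   the dispersion converges;
2. *common dispersion* by maximising the conditional log-likelihood of
   the within-group count splits given the group totals;
3. *exact test*: conditional on the total z = z1 + z2 of each site, the
   group-1 sum follows a negative hypergeometric law (binomial in the
   Poisson limit phi = 0); the two-sided p-value doubles the smaller tail
   (observed point included in both) and is capped at 1;
4. multiple testing by Benjamini-Hochberg (default) or Bonferroni.

`logFC` is the log2 female/male ratio of prior-damped mean CPM, so a site
more methylated in males has a negative logFC.

The public surface is statsmodels-like: build a :class:`MethylDiffModel`
from a :class:`~methylrad.sites.CountMatrix`, call :meth:`fit`, inspect
the returned :class:`MethylDiffResults`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .sites import CountMatrix

FEMALE, MALE = "female", "male"
DIRECTION_FEMALE = "higher-in-female"
DIRECTION_MALE = "higher-in-male"

PHI_BOUNDS = (1e-6, 10.0)


@dataclass(frozen=True)
class DispersionEstimate:
    common: float
    tagwise: np.ndarray | None = None
    prior_weight: float = 10.0


# ---------------------------------------------------------------------------
# library equalization (quantile adjustment)
# ---------------------------------------------------------------------------

def _q2q_nbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Quantile mapping of counts between NB distributions.

    Maps ``x ~ NB(input_mean, phi)`` to the matching quantile of
    ``NB(output_mean, phi)`` using the average of a normal and a gamma
    continuous approximation (the standard continuity device; exact
    integer inversion would make the pseudo-counts lumpy).
    """
    x = np.asarray(x, dtype=float)
    im = np.where(input_mean < 1e-14, input_mean + 0.25, input_mean)
    om = np.where(output_mean < 1e-14, output_mean + 0.25, output_mean)
    ri = 1.0 + dispersion * im
    ro = 1.0 + dispersion * om
    vi = im * ri
    vo = om * ro

    out = np.empty_like(x)
    upper = x >= im
    for mask, tail_upper in ((upper, True), (~upper, False)):
        if not mask.any():
            continue
        xm, imm, omm = x[mask], im[mask], om[mask]
        rim, rom = ri[mask], ro[mask]
        vim, vom = vi[mask], vo[mask]
        if tail_upper:
            p_norm = stats.norm.sf(xm, loc=imm, scale=np.sqrt(vim))
            p_gam = stats.gamma.sf(xm, a=imm / rim, scale=rim)
            q_norm = stats.norm.isf(p_norm, loc=omm, scale=np.sqrt(vom))
            q_gam = stats.gamma.isf(p_gam, a=omm / rom, scale=rom)
        else:
            p_norm = stats.norm.cdf(xm, loc=imm, scale=np.sqrt(vim))
            p_gam = stats.gamma.cdf(xm, a=imm / rim, scale=rim)
            q_norm = stats.norm.ppf(p_norm, loc=omm, scale=np.sqrt(vom))
            q_gam = stats.gamma.ppf(p_gam, a=omm / rom, scale=rom)
        out[mask] = 0.5 * (q_norm + q_gam)
    return np.maximum(out, 0.0)


def equalize_libraries(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    group_masks: list[np.ndarray],
    dispersion: float,
) -> tuple[np.ndarray, float]:
    """Map counts to pseudo-counts at the common (geometric-mean) library
    size; per-site expected proportions are estimated within group."""
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(lib_sizes))))
    input_mean = np.zeros_like(counts, dtype=float)
    output_mean = np.zeros_like(counts, dtype=float)
    for mask in group_masks:
        z = counts[:, mask].sum(axis=1)
        p = z / lib_sizes[mask].sum()  # per-site proportion within group
        input_mean[:, mask] = np.outer(p, lib_sizes[mask])
        output_mean[:, mask] = np.outer(p, np.full(mask.sum(), common))
    pseudo = _q2q_nbinom(counts, input_mean, output_mean, dispersion)
    return pseudo, common


# ---------------------------------------------------------------------------
# conditional likelihood / dispersion
# ---------------------------------------------------------------------------

def conditional_log_likelihood(
    pseudo: np.ndarray, group_masks: list[np.ndarray], phi: float
) -> float:
    """Summed conditional log-likelihood of within-group splits given the
    group totals, at dispersion ``phi`` (equalized libraries assumed):
    per group, l(phi) = sum_i lnG(y_i + r) + lnG(n r) - lnG(z + n r)
    - n lnG(r) with r = 1/phi."""
    r = 1.0 / phi
    total = 0.0
    for mask in group_masks:
        y = pseudo[:, mask]
        n = int(mask.sum())
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            + len(z) * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
            - len(z) * n * gammaln(r)
        )
    return total


def estimate_common_dispersion(
    pseudo: np.ndarray, group_masks: list[np.ndarray]
) -> float:
    """Maximise the conditional log-likelihood over phi in [1e-6, 10]."""
    if pseudo.size == 0 or not np.any(pseudo.sum(axis=1) > 0):
        raise ValueError("all sites have zero counts; dispersion undefined")
    res = optimize.minimize_scalar(
        lambda phi: -conditional_log_likelihood(pseudo, group_masks, phi),
        bounds=PHI_BOUNDS,
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def estimate_tagwise_dispersion(
    pseudo: np.ndarray,
    group_masks: list[np.ndarray],
    common: float,
    prior_weight: float = 10.0,
) -> np.ndarray:
    """Empirical-Bayes per-site dispersions shrunk towards the common one.

    Each site maximises its own conditional likelihood plus
    ``prior_weight`` times the average per-site likelihood of the whole
    matrix (a weighted-likelihood shrinkage; off by default in the model).
    """
    n_sites = pseudo.shape[0]
    out = np.empty(n_sites)
    for i in range(n_sites):
        row = pseudo[i : i + 1, :]

        def neg(phi: float) -> float:
            own = conditional_log_likelihood(row, group_masks, phi)
            pooled = conditional_log_likelihood(pseudo, group_masks, phi) / n_sites
            return -(own + prior_weight * pooled)

        res = optimize.minimize_scalar(
            neg, bounds=PHI_BOUNDS, method="bounded", options={"xatol": 1e-5}
        )
        out[i] = res.x
    return out


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _conditional_pmf(z: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """P(S1 = k | S1 + S2 = z) for k = 0..z.

    S_g is a sum of n_g i.i.d. NB(m, phi) counts, i.e. NB(n_g m, phi/n_g);
    conditioning cancels m and yields a negative hypergeometric pmf with
    shape parameters r_g = n_g / phi.  phi = 0 is the binomial limit."""
    k = np.arange(z + 1)
    if phi <= 0:
        return stats.binom.pmf(k, z, n1 / (n1 + n2))
    r1, r2 = n1 / phi, n2 / phi
    logpmf = (
        gammaln(k + r1) - gammaln(k + 1) - gammaln(r1)
        + gammaln(z - k + r2) - gammaln(z - k + 1) - gammaln(r2)
    )
    return np.exp(logpmf - logsumexp(logpmf))


def exact_test(
    pseudo: np.ndarray,
    group_masks: list[np.ndarray],
    phi: float,
) -> np.ndarray:
    """Two-sided conditional exact test p-value per site.

    Group sums are rounded to integers (pseudo-counts are continuous);
    p = min(1, 2 * min(lower tail, upper tail)) with the observed count
    included in both tails; z = 0 gives p = 1 by convention.
    """
    n1 = int(group_masks[0].sum())
    n2 = int(group_masks[1].sum())
    s1 = np.rint(pseudo[:, group_masks[0]].sum(axis=1)).astype(int)
    s2 = np.rint(pseudo[:, group_masks[1]].sum(axis=1)).astype(int)
    pvals = np.ones(len(s1))
    cache: dict[int, np.ndarray] = {}
    for i, (k, z) in enumerate(zip(s1, s1 + s2)):
        if z == 0:
            continue
        cum = cache.get(z)
        if cum is None:
            pmf = _conditional_pmf(z, n1, n2, phi)
            cum = np.cumsum(pmf)
            cache[z] = cum
        lower = cum[k]
        upper = 1.0 - (cum[k - 1] if k > 0 else 0.0)
        pvals[i] = min(1.0, 2.0 * min(lower, upper))
    return pvals


# ---------------------------------------------------------------------------
# effect sizes and multiplicity
# ---------------------------------------------------------------------------

def compute_logfc_logcpm(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    group_masks: list[np.ndarray],
    prior: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """logFC = log2((mean female CPM + prior)/(mean male CPM + prior));
    logCPM = log2(across-sample mean CPM + prior).  group_masks[0] is the
    female group.  ``prior`` damps zero counts and must be > 0."""
    if prior <= 0:
        raise ValueError("prior must be > 0")
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = counts / lib_sizes * 1e6
    mean_f = cpm[:, group_masks[0]].mean(axis=1)
    mean_m = cpm[:, group_masks[1]].mean(axis=1)
    logfc = np.log2(mean_f + prior) - np.log2(mean_m + prior)
    logcpm = np.log2(cpm.mean(axis=1) + prior)
    return logfc, logcpm


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def call_dms(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significance and direction calls on a fitted results table.

    Adds ``significant`` (adjP < alpha) and ``direction`` (higher-in-female
    iff logFC > 0).  Direction tallies partition the significant set.
    """
    out = table.copy()
    out["significant"] = out["adjP"] < alpha
    out["direction"] = np.where(out["logFC"] > 0, DIRECTION_FEMALE, DIRECTION_MALE)
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class MethylDiffModel:
    """Two-group NB exact-test differential methylation model.

    Parameters
    ----------
    matrix:
        Coverage-filtered count matrix with female/male group labels.
    alpha:
        Adjusted-p significance threshold for DMS calls.
    adjust:
        ``"bh"`` (default, the FDR < alpha convention) or ``"bonferroni"``.
    prior_cpm:
        Prior added to mean CPM for logFC/logCPM stability.
    tagwise:
        Also estimate empirical-Bayes tagwise dispersions (diagnostic
        only; the exact test always uses the common dispersion).
    """

    def __init__(
        self,
        matrix: CountMatrix,
        *,
        alpha: float = 0.05,
        adjust: str = "bh",
        prior_cpm: float = 0.5,
        max_iter: int = 3,
        tol: float = 1e-4,
        tagwise: bool = False,
    ) -> None:
        labels = set(matrix.groups)
        if labels != {FEMALE, MALE}:
            raise ValueError(f"expected groups {{female, male}}, got {sorted(labels)}")
        if matrix.counts.shape[1] < 2:
            raise ValueError("need at least two samples")
        self.matrix = matrix
        self.alpha = alpha
        self.adjust = adjust
        self.prior_cpm = prior_cpm
        self.max_iter = max_iter
        self.tol = tol
        self.tagwise = tagwise
        groups = matrix.groups.values
        self.group_masks = [groups == FEMALE, groups == MALE]

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, groups: pd.Series, **kwargs
    ) -> "MethylDiffModel":
        """Build from a sites x samples frame (index = site keys) and a
        sample -> group series."""
        matrix = CountMatrix(counts=counts, groups=groups)
        return cls(matrix, **kwargs)

    def fit(self) -> "MethylDiffResults":
        counts = self.matrix.counts.to_numpy(dtype=float)
        libs = self.matrix.library_sizes.to_numpy(dtype=float)
        masks = self.group_masks

        phi = 0.01
        for _ in range(self.max_iter):
            pseudo, common = equalize_libraries(counts, libs, masks, phi)
            phi_new = estimate_common_dispersion(pseudo, masks)
            converged = abs(phi_new - phi) < self.tol
            phi = phi_new
            if converged:
                break
        pseudo, common = equalize_libraries(counts, libs, masks, phi)

        tagwise = (
            estimate_tagwise_dispersion(pseudo, masks, phi) if self.tagwise else None
        )
        dispersion = DispersionEstimate(common=phi, tagwise=tagwise)

        pvals = exact_test(pseudo, masks, phi)
        logfc, logcpm = compute_logfc_logcpm(counts, libs, masks, self.prior_cpm)
        adj = adjust_pvalues(pvals, self.adjust)
        table = pd.DataFrame(
            {"logFC": logfc, "logCPM": logcpm, "PValue": pvals, "adjP": adj},
            index=self.matrix.counts.index,
        )
        table = call_dms(table, self.alpha)
        return MethylDiffResults(
            model=self,
            table=table,
            dispersion=dispersion,
            common_lib_size=common,
            pseudo_counts=pd.DataFrame(
                pseudo, index=self.matrix.counts.index,
                columns=self.matrix.counts.columns,
            ),
        )


@dataclass
class MethylDiffResults:
    """Fitted differential-methylation results.

    ``table`` holds one row per site: logFC (log2 female/male), logCPM,
    PValue, adjP, significant, direction.
    """

    model: MethylDiffModel
    table: pd.DataFrame
    dispersion: DispersionEstimate
    common_lib_size: float
    pseudo_counts: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def dms(self) -> pd.DataFrame:
        """The significant subset (the DMS table)."""
        return self.table[self.table.significant]

    def direction_tallies(self) -> dict[str, int]:
        d = self.dms()["direction"].value_counts().to_dict()
        return {
            DIRECTION_FEMALE: int(d.get(DIRECTION_FEMALE, 0)),
            DIRECTION_MALE: int(d.get(DIRECTION_MALE, 0)),
        }

    def chromosome_density(self, contig_lengths: dict[str, int]) -> pd.DataFrame:
        """Per-contig methylated-site and DMS densities (count and /Mb)."""
        from .annotate import chromosome_density

        sites = self.table.reset_index()[["contig", "pos", "strand"]]
        dms = self.dms().reset_index()[["contig", "pos", "strand"]]
        return chromosome_density(sites, dms, contig_lengths)

    def to_table(self) -> pd.DataFrame:
        """Flat TSV-ready table mirroring the reporting layout:
        site key, per-sample counts, logFC, logCPM, PValue, adjP, direction."""
        counts = self.model.matrix.counts
        out = counts.reset_index()
        out.insert(0, "site", [f"{c}_{p}" for c, p, _ in counts.index])
        stats_part = self.table.reset_index(drop=True)[
            ["logFC", "logCPM", "PValue", "adjP", "significant", "direction"]
        ]
        return pd.concat([out, stats_part], axis=1)

    def summary(self) -> str:
        tall = self.direction_tallies()
        lines = [
            "Differential methylation (NB exact test, qCML dispersion)",
            "=" * 58,
            f"sites tested:            {self.n_sites}",
            f"samples:                 {len(self.model.matrix.samples)} "
            f"({int(self.model.group_masks[0].sum())} female, "
            f"{int(self.model.group_masks[1].sum())} male)",
            f"common dispersion:       {self.dispersion.common:.4f}",
            f"common library size:     {self.common_lib_size:.1f}",
            f"adjustment:              {self.model.adjust}",
            f"alpha:                   {self.model.alpha}",
            f"DMSs (adjP < alpha):     {int(self.table.significant.sum())}",
            f"  higher in female:      {tall[DIRECTION_FEMALE]}",
            f"  higher in male:        {tall[DIRECTION_MALE]}",
        ]
        return "\n".join(lines)
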
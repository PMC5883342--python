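"""Genotype-phenotype association on non-diploid calls.

Per-SNP case-control testing uses the Pearson chi-squared statistic on a 2x2
allele-by-phenotype table (no continuity correction, 1 df).  Multiple-testing
correction is Bonferroni over the *effective* number of independent tests
Meff, estimated from the eigenvalues of the genotype-dosage correlation
matrix by the Li & Ji rule

    Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]

which counts each eigenvalue's integer part as one independent test when it
reaches 1 and its fractional part as a partial test.  Published Meff values
from other estimators can equally be supplied as scope inputs.

The combined two-group analysis fits a logistic regression of the binary
phenotype on diagnosis, genotype risk-group and their interaction, reporting
a likelihood-ratio test against the intercept-only model and Nagelkerke's
rescaled pseudo-R-squared.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Diagnosis, GenotypeState, NonDiploidCall, PhenotypeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d: rows are genotype groups, columns (affected, unaffected)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def chisq_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table, without continuity correction.

    Returns ``(chi2, p)`` with p from the upper tail of chi-squared(1 df),
    using the closed form ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``.
    A table with a zero row or column margin carries no information about
    association; it yields ``(0.0, 1.0)`` with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        warnings.warn("degenerate 2x2 margins: chi-squared undefined, reporting chi2=0, p=1")
        return 0.0, 1.0
    chi2 = table.n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass(frozen=True)
class EffectiveTestCount:
    """Effective number of independent tests among correlated SNPs."""

    scope: str
    m_snps: int
    meff: float
    eigenvalues: tuple[float, ...]


def dosage_matrix(calls: Iterable[NonDiploidCall]) -> pd.DataFrame:
    """Samples-by-SNPs matrix of B-allele dosages (haploid 0/1, triploid 0..3);
    no-calls are NaN."""
    rows = [
        {
            "sample_id": c.sample_id,
            "snp_id": c.snp_id,
            "dosage": np.nan if not c.is_called else float(c.b_allele_count),
        }
        for c in calls
    ]
    if not rows:
        raise ValueError("no calls supplied")
    df = pd.DataFrame(rows)
    return df.pivot_table(index="sample_id", columns="snp_id", values="dosage", aggfunc="first")


def effective_num_tests(
    genotypes: pd.DataFrame | np.ndarray,
    scope: str = "locus",
) -> EffectiveTestCount:
    """Estimate Meff from a samples-by-SNPs dosage matrix (Li & Ji rule).

    Monomorphic SNPs (zero variance among non-missing dosages) are dropped
    before computing the pairwise-complete Pearson correlation matrix.
    Requires at least 2 samples and 1 polymorphic SNP.
    """
    df = pd.DataFrame(genotypes)
    if df.shape[0] < 2:
        raise ValueError("Meff estimation needs at least 2 samples")
    variances = df.var(axis=0, skipna=True)
    poly = df.loc[:, (variances > 0).to_numpy()]
    if poly.shape[1] < 1:
        raise ValueError("Meff estimation needs at least 1 polymorphic SNP")

    corr = poly.corr(method="pearson", min_periods=2)  # pairwise-complete
    mat = corr.to_numpy()
    # SNP pairs with no overlapping samples get correlation 0
    mat[np.isnan(mat)] = 0.0
    np.fill_diagonal(mat, 1.0)
    mat = (mat + mat.T) / 2.0
    lam = np.linalg.eigvalsh(mat)
    # pairwise-complete matrices need not be PSD; tiny negatives are noise.
    # Rounding protects the integer-floor rule from fp error at exact-integer
    # eigenvalues (e.g. a duplicated SNP's lambda = 2).
    lam = np.round(np.clip(lam, 0.0, None), 10)
    meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    m = poly.shape[1]
    meff = min(max(meff, 1.0), float(m))
    return EffectiveTestCount(
        scope=scope,
        m_snps=m,
        meff=meff,
        eigenvalues=tuple(float(x) for x in sorted(lam, reverse=True)),
    )


def bonferroni_adjust(p: float, meff: float) -> float:
    """Bonferroni-adjusted p over ``meff`` effective tests: min(1, p * meff)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if meff < 1.0:
        raise ValueError(f"meff must be >= 1, got {meff}")
    return min(1.0, p * meff)


def significance_threshold(alpha: float, meff: float) -> float:
    """Uncorrected-p threshold equivalent to family-wise level ``alpha``: alpha / meff."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if meff < 1.0:
        raise ValueError(f"meff must be >= 1, got {meff}")
    return alpha / meff


@dataclass(frozen=True)
class MeffScope:
    """A multiple-testing scope: the gene labels it covers and its Meff.

    ``genes=None`` marks the catch-all (locus-wide) scope applied to SNPs not
    covered by any named scope — mirroring a two-tier correction where an
    a-priori candidate gene gets its own, smaller Meff.
    """

    meff: float
    genes: Optional[frozenset[str]] = None
    label: str = ""

    def covers(self, gene: str) -> bool:
        return self.genes is None or gene in self.genes


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    gene: str
    table: ContingencyTable2x2
    chi2: Optional[float]
    p_uncorrected: Optional[float]
    p_bonferroni: Optional[float]
    meff_used: Optional[float]
    chrom: Optional[str] = None
    pos: Optional[int] = None
    untestable: bool = False

    @property
    def neglog10_p(self) -> Optional[float]:
        if self.p_uncorrected is None or self.p_uncorrected <= 0:
            return None
        return -math.log10(self.p_uncorrected)


def _risk_group(call: NonDiploidCall) -> Optional[int]:
    """Binary allele grouping: 1 = B-allele group, 0 = A-allele group.

    Haploid samples group by allele identity; triploid samples by majority
    allele (at least 2 of 3 copies B).  No-calls return None.
    """
    if not call.is_called:
        return None
    if call.copy_number == 1:
        return call.b_allele_count
    return 1 if call.b_allele_count >= 2 else 0


def region_scan(
    calls: Iterable[NonDiploidCall],
    phenotypes: Sequence[PhenotypeRecord],
    gene_map: Optional[Mapping[str, str]] = None,
    scopes: Optional[Sequence[MeffScope]] = None,
) -> list[AssociationResult]:
    """Per-SNP chi-squared scan of genotype against the binary phenotype.

    ``calls`` must come from samples of a single diagnosis group; samples
    with a no-call at a SNP are dropped from that SNP's table only (pairwise
    deletion).  Each SNP is Bonferroni-corrected with the Meff of the first
    scope covering its gene (a catch-all scope has ``genes=None``); with no
    scopes, ``p_bonferroni`` is left unset.  SNPs that are monomorphic or
    have fewer than 2 informative samples are flagged untestable and sort
    last.  Output is sorted by uncorrected p.
    """
    pheno = {p.sample_id: p for p in phenotypes}
    calls = list(calls)
    diagnoses = {pheno[c.sample_id].diagnosis for c in calls if c.sample_id in pheno}
    if len(diagnoses) > 1:
        raise ValueError(
            "region_scan expects calls from a single diagnosis group; "
            f"got {sorted(d.value for d in diagnoses)}"
        )

    by_snp: dict[str, list[NonDiploidCall]] = {}
    for c in calls:
        by_snp.setdefault(c.snp_id, []).append(c)

    results: list[AssociationResult] = []
    for snp_id, snp_calls in by_snp.items():
        counts = [[0, 0], [0, 0]]  # rows: risk group 1/0; cols: affected/unaffected
        n_informative = 0
        for c in snp_calls:
            ph = pheno.get(c.sample_id)
            g = _risk_group(c)
            if ph is None or g is None:
                continue
            counts[1 - g][0 if ph.affected else 1] += 1
            n_informative += 1
        gene = (gene_map or {}).get(snp_id, "intergenic")
        chrom = snp_calls[0].chrom
        pos = snp_calls[0].pos
        table = ContingencyTable2x2(
            a=counts[0][0], b=counts[0][1], c=counts[1][0], d=counts[1][1]
        ) if n_informative else None

        monomorphic = table is None or table.a + table.b == 0 or table.c + table.d == 0
        if n_informative < 2 or monomorphic:
            results.append(
                AssociationResult(
                    snp_id=snp_id, gene=gene, chrom=chrom, pos=pos,
                    table=table or ContingencyTable2x2(0, 1, 0, 0),
                    chi2=None, p_uncorrected=None, p_bonferroni=None,
                    meff_used=None, untestable=True,
                )
            )
            continue

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p = chisq_2x2(table)
        meff_used = None
        p_bonf = None
        for scope in scopes or []:
            if scope.covers(gene):
                meff_used = scope.meff
                p_bonf = bonferroni_adjust(p, meff_used)
                break
        results.append(
            AssociationResult(
                snp_id=snp_id, gene=gene, chrom=chrom, pos=pos, table=table,
                chi2=chi2, p_uncorrected=p, p_bonferroni=p_bonf,
                meff_used=meff_used, untestable=False,
            )
        )

    results.sort(key=lambda r: (r.untestable, r.p_uncorrected if r.p_uncorrected is not None else 2.0, r.snp_id))
    n_testable = sum(not r.untestable for r in results)
    logger.info("region_scan: %d SNPs tested, %d untestable", n_testable, len(results) - n_testable)
    return results


def manhattan_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Plot-ready table (chrom, pos, snp_id, gene, -log10 p) of testable SNPs, by position."""
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "snp_id": r.snp_id,
            "gene": r.gene,
            "neglog10_p": r.neglog10_p,
        }
        for r in results
        if not r.untestable
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "snp_id", "gene", "neglog10_p"]).sort_values(
        ["chrom", "pos"], ignore_index=True
    )


def majority_allele_coding(
    calls: Iterable[NonDiploidCall],
    snp_id: str,
    risk_allele: str = "B",
) -> dict[str, int]:
    """Per-sample binary risk-group coding at one SNP.

    Haploid samples are coded by allele identity, triploid samples by
    whether at least 2 of the 3 copies carry the risk allele.  No-calls are
    omitted.  ``risk_allele`` selects which abstract allele (A or B) counts
    as the risk group (coded 1).
    """
    if risk_allele not in ("A", "B"):
        raise ValueError("risk_allele must be 'A' or 'B'")
    coding: dict[str, int] = {}
    for c in calls:
        if c.snp_id != snp_id:
            continue
        g = _risk_group(c)
        if g is None:
            continue
        coding[c.sample_id] = g if risk_allele == "B" else 1 - g
    return coding


@dataclass(frozen=True)
class InteractionFit:
    """Logistic fit of phenotype ~ diagnosis * genotype with pseudo-R-squared."""

    coefficients: dict  # intercept, diagnosis, genotype, interaction (log-odds)
    loglik_full: float
    loglik_null: float
    nagelkerke_r2: Optional[float]
    model_p: float
    separation_flag: bool
    n: int
    converged: bool = True
    fitted_probs: tuple[float, ...] = field(default_factory=tuple)


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> Optional[float]:
    """Nagelkerke's rescaled Cox-Snell pseudo-R-squared.

    ``R2_CS = 1 - exp(2 (ll_null - ll_full) / n)`` rescaled by its maximum
    ``R2_max = 1 - exp(2 ll_null / n)`` so the statistic can reach 1.
    Undefined (None, with a warning) when the null log-likelihood is 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("full-model log-likelihood must be >= null log-likelihood")
    r2_cs = 1.0 - math.exp(2.0 * (loglik_null - loglik_full) / n)
    r2_max = 1.0 - math.exp(2.0 * loglik_null / n)
    if r2_max <= 0.0:
        warnings.warn("null log-likelihood is 0: Nagelkerke R2 undefined")
        return None
    return min(max(r2_cs / r2_max, 0.0), 1.0)


def logistic_interaction(
    phenotypes: Sequence[PhenotypeRecord],
    genotype_coding: Mapping[str, int],
) -> InteractionFit:
    """Fit phenotype ~ diagnosis + genotype + diagnosis:genotype by maximum likelihood.

    ``genotype_coding`` maps sample id to a binary risk-group indicator (see
    :func:`majority_allele_coding`); samples absent from it are excluded.
    Both diagnosis groups must be present.  The model p is the
    likelihood-ratio test of the full model against intercept-only (3 df);
    ``separation_flag`` is set when any fitted probability is within 1e-6 of
    0 or 1 (the corresponding coefficient is then at the boundary and its
    magnitude is not interpretable).
    """
    import statsmodels.api as sm

    rows = []
    for p in phenotypes:
        if p.sample_id not in genotype_coding:
            continue
        rows.append(
            {
                "y": int(p.affected),
                "dx": 1 if p.diagnosis is Diagnosis.DUP else 0,
                "g": int(genotype_coding[p.sample_id]),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["dx"].nunique() < 2:
        raise ValueError("logistic_interaction requires samples from both diagnosis groups")
    if df["y"].nunique() < 2:
        raise ValueError("outcome is constant: model not identifiable")

    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "diagnosis": df["dx"].astype(float),
            "genotype": df["g"].astype(float),
            "interaction": (df["dx"] * df["g"]).astype(float),
        }
    )
    # drop constant predictors (e.g. genotype monomorphic in these samples)
    keep = ["intercept"] + [c for c in ("diagnosis", "genotype", "interaction") if X[c].nunique() > 1]
    Xk = X[keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(df["y"].to_numpy(), Xk.to_numpy(), family=sm.families.Binomial())
        try:
            fit = model.fit(maxiter=100, tol=1e-8)
            converged = bool(fit.converged)
        except Exception:  # pragma: no cover - numerical failure path
            fit = model.fit(maxiter=100, tol=1e-8, method="lbfgs")
            converged = False
        null_model = sm.GLM(df["y"].to_numpy(), np.ones((len(df), 1)), family=sm.families.Binomial())
        null_fit = null_model.fit()

    ll_full = float(fit.llf)
    ll_null = float(null_fit.llf)
    probs = np.asarray(fit.fittedvalues, dtype=float)
    separation = bool(np.any(probs < 1e-6) or np.any(probs > 1.0 - 1e-6))
    if not converged:
        warnings.warn("logistic_interaction: IRLS did not converge; coefficients are partial")

    coefs = {name: float(v) for name, v in zip(keep, fit.params)}
    for name in ("diagnosis", "genotype", "interaction"):
        coefs.setdefault(name, 0.0)
    df_diff = Xk.shape[1] - 1
    lr = max(0.0, 2.0 * (ll_full - ll_null))
    model_p = float(stats.chi2.sf(lr, df=max(df_diff, 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = nagelkerke_r2(max(ll_full, ll_null), ll_null, len(df))
    return InteractionFit(
        coefficients=coefs,
        loglik_full=ll_full,
        loglik_null=ll_null,
        nagelkerke_r2=r2,
        model_p=model_p,
        separation_flag=separation,
        n=len(df),
        converged=converged,
        fitted_probs=tuple(float(x) for x in probs),
    )
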
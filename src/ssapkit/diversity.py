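"""Null-allele frequencies and gene diversity from dominant markers.

Band absence at a dominant locus is the recessive phenotype: under full
inbreeding (F_IS = 1) every individual is homozygous, so the probability
of showing no band equals the null-allele frequency q directly, and the
binomial count of band-free accessions yields a Beta posterior for q.
The Bayesian treatment (Zhivotovsky-style, as implemented in standard
dominant-marker software) uses a Beta prior fitted by moments to the
among-locus distribution of observed absence fractions, which shrinks
per-locus estimates away from 0/1 boundaries at small sample sizes.

Per taxon and TE family we report the number of bands, the proportion of
polymorphic loci at a frequency threshold, and Nei's gene diversity
H = mean over loci of 2q(1-q), with its among-locus standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .marker_data import MarkerMatrix, TaxonScheme, ValidationError

__all__ = [
    "DiversityConfig",
    "DiversityEstimate",
    "fit_beta_prior",
    "bayes_null_freq",
    "nei_diversity_profile",
]


@dataclass(frozen=True)
class DiversityConfig:
    """Settings for dominant-marker diversity estimation.

    f_is
        Inbreeding coefficient in [0, 1]; 1 (the default, appropriate for
        highly selfing material) makes the absence phenotype probability
        equal q and the posterior conjugate.
    prior
        'moment_fitted' fits a Beta prior to the observed among-locus
        absence fractions; 'uniform' uses Beta(1, 1).
    polymorphism_threshold
        A locus counts as polymorphic when its minor allele frequency
        min(q, 1-q) is at least this value (default 0.05, the "5% level").
    """

    f_is: float = 1.0
    prior: str = "moment_fitted"
    polymorphism_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_is <= 1.0:
            raise ValidationError("f_is must be in [0, 1]")
        if not 0.0 < self.polymorphism_threshold <= 0.5:
            raise ValidationError("polymorphism threshold must be in (0, 0.5]")
        if self.prior not in ("uniform", "moment_fitted"):
            raise ValidationError(f"unknown prior {self.prior!r}")


def fit_beta_prior(absence_freqs: np.ndarray | list[float]) -> tuple[float, float]:
    """Method-of-moments Beta fit to observed per-locus absence fractions.

    With among-locus mean m and variance v the fit is
    a = m(m(1-m)/v - 1), b = (1-m)(m(1-m)/v - 1).  Degenerate inputs
    (zero variance, variance >= m(1-m), or a non-positive parameter) fall
    back to the uniform prior (1, 1).
    """
    x = np.asarray(absence_freqs, dtype=float)
    if x.size == 0:
        raise ValidationError("no absence frequencies supplied")
    if x.size < 2:
        return (1.0, 1.0)
    m = float(x.mean())
    v = float(x.var(ddof=0))
    if v <= 0 or m <= 0 or m >= 1 or v >= m * (1 - m):
        return (1.0, 1.0)
    common = m * (1 - m) / v - 1
    a, b = m * common, (1 - m) * common
    if a <= 0 or b <= 0:
        return (1.0, 1.0)
    return (a, b)


def _absence_prob(q: np.ndarray, f_is: float) -> np.ndarray:
    # P(no band) for a dominant locus: homozygous-null probability
    return q * q + f_is * q * (1 - q)


def bayes_null_freq(
    n_absent: int, n: int, prior: tuple[float, float],
    cfg: DiversityConfig = DiversityConfig(),
) -> float:
    """Posterior-mean null-allele frequency from a dominant-marker count.

    With F_IS = 1 the likelihood is Binomial(n, q) in the absence count
    and the posterior is Beta(a + n_absent, b + n - n_absent), giving the
    closed form (n_absent + a) / (n + a + b).  For F_IS < 1 the absence
    probability is q^2 + F_IS q(1-q) and the posterior mean is obtained
    by numerical integration.
    """
    if not 0 <= n_absent <= n or n < 1:
        raise ValidationError(f"invalid counts n_absent={n_absent}, n={n}")
    a, b = prior
    if cfg.f_is == 1.0:
        return (n_absent + a) / (n + a + b)
    def integrand(q: np.ndarray, extra: int) -> np.ndarray:
        p = _absence_prob(np.asarray(q), cfg.f_is)
        return (q ** (a - 1 + extra) * (1 - q) ** (b - 1)
                * p ** n_absent * (1 - p) ** (n - n_absent))
    num, _ = integrate.quad(integrand, 0, 1, args=(1,), limit=200)
    den, _ = integrate.quad(integrand, 0, 1, args=(0,), limit=200)
    return num / den


@dataclass(frozen=True)
class DiversityEstimate:
    """Per-taxon, per-TE dominant-marker diversity summary."""

    taxon: str
    te_family: str
    n_accessions: int
    n_loci: int
    band_count: int
    q_hat: pd.Series                  # locus -> posterior-mean null frequency
    prior: tuple[float, float]
    proportion_polymorphic: float
    gene_diversity: float
    gene_diversity_se: float

    def __post_init__(self) -> None:
        q = self.q_hat.to_numpy()
        if not ((q > 0) & (q < 1)).all():
            raise ValidationError("q estimates must lie strictly in (0, 1)")
        if not 0 <= self.gene_diversity <= 0.5 or self.gene_diversity_se < 0:
            raise ValidationError("invalid diversity summary")


def nei_diversity_profile(
    m: MarkerMatrix, s: TaxonScheme, taxon: str,
    cfg: DiversityConfig = DiversityConfig(),
) -> DiversityEstimate:
    """Estimate null-allele frequencies and Nei's gene diversity for one taxon.

    Loci scored for the TE family (i.e. with at least one presence call in
    the whole matrix) enter the estimate; loci absent from every accession
    of the dataset are flagged upstream and skipped here.  The Beta prior
    is fitted per taxon from the observed absence fractions, with loci
    monomorphic for presence contributing an absence fraction of 0.
    """
    s.check_matrix(m)
    accs = [a for a in m.accession_ids if s.taxon_of[a] == taxon]
    if len(accs) < 2:
        raise ValidationError(
            f"taxon {taxon!r} has {len(accs)} accession(s); need >= 2 for "
            "diversity estimation")
    idx = [m.accession_ids.index(a) for a in accs]
    calls = m.calls[:, idx]
    scored = m.calls.sum(axis=1) > 0        # drop dataset-wide empty loci
    calls = calls[scored]
    loci = [l for l, keep in zip(m.locus_ids, scored) if keep]
    n = len(accs)
    n_absent = (calls == 0).sum(axis=1)
    absence_freqs = n_absent / n
    prior = (1.0, 1.0) if cfg.prior == "uniform" else fit_beta_prior(absence_freqs)
    q = np.array([bayes_null_freq(int(k), n, prior, cfg) for k in n_absent])
    h_loc = 2 * q * (1 - q)
    h = float(h_loc.mean())
    se = float(h_loc.std(ddof=1) / np.sqrt(len(h_loc))) if len(h_loc) > 1 else 0.0
    minor = np.minimum(q, 1 - q)
    return DiversityEstimate(
        taxon=taxon,
        te_family=m.te_family,
        n_accessions=n,
        n_loci=len(loci),
        band_count=int((calls.sum(axis=1) > 0).sum()),
        q_hat=pd.Series(q, index=loci),
        prior=prior,
        proportion_polymorphic=float((minor >= cfg.polymorphism_threshold).mean()),
        gene_diversity=h,
        gene_diversity_se=se,
    )
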
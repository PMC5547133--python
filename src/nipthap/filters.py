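"""Site-level quality filters for maternal plasma allele counts.

Four pure predicates, each matching a threshold of the plasma SNP-detection
pipeline the analysis consumes:

* minimum depth — drop sites covered by fewer than 40 reads;
* minor-allele presence — retain sites whose alternate-allele ratio exceeds
  1% with Beta-posterior support (Beta(1,1) prior, 0.99 credibility);
* strand bias — two-sided Fisher exact test on the ref/alt x fwd/rev table,
  drop at P < 1e-4;
* in-read position bias — two-sample Kolmogorov-Smirnov test of ref vs alt
  read offsets, drop at P < 1e-6.

Each predicate is independent, so the pipeline outcome does not depend on
the order in which filters are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlasmaSite:
    """Per-site plasma observation: allele depths with optional strand counts
    and in-read position lists."""

    chrom: str
    pos: int
    dep_ref: int
    dep_alt: int
    fwd_ref: int | None = None
    rev_ref: int | None = None
    fwd_alt: int | None = None
    rev_alt: int | None = None
    read_positions_ref: tuple[int, ...] | None = None
    read_positions_alt: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.dep_ref < 0 or self.dep_alt < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative depth")
        strand = (self.fwd_ref, self.rev_ref, self.fwd_alt, self.rev_alt)
        if any(s is not None for s in strand):
            if any(s is None or s < 0 for s in strand):
                raise ValueError(f"{self.chrom}:{self.pos}: incomplete strand counts")
            if self.fwd_ref + self.rev_ref != self.dep_ref or self.fwd_alt + self.rev_alt != self.dep_alt:
                raise ValueError(f"{self.chrom}:{self.pos}: strand counts do not sum to depths")

    @property
    def depth(self) -> int:
        return self.dep_ref + self.dep_alt

    @property
    def has_strand(self) -> bool:
        return self.fwd_ref is not None


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the plasma site filters.

    ``allele_ratio_enabled`` exists because the >1% minor-allele rule is a
    variant-*discovery* criterion: when counting alleles at panel sites whose
    genotypes are already known from parental gDNA, a near-zero alternate
    ratio is an expected signal (the fetus did not inherit the allele), not
    an artifact, so the pipeline disables this predicate for panel-joined
    counts while keeping it for de novo plasma site lists.
    """

    min_depth: int = 40
    min_allele_ratio: float = 0.01
    ratio_credibility: float = 0.99
    strand_bias_p: float = 1e-4
    position_bias_p: float = 1e-6
    allele_ratio_enabled: bool = True


@dataclass
class FilterResult:
    site: PlasmaSite
    failed: list[str] = field(default_factory=list)

    @property
    def keep(self) -> bool:
        return not self.failed


def filter_depth(site: PlasmaSite, min_depth: int = 40) -> bool:
    """Keep iff total depth is at least ``min_depth`` reads."""
    return site.depth >= min_depth


def filter_allele_ratio(
    site: PlasmaSite,
    min_ratio: float = 0.01,
    credibility: float = 0.99,
) -> bool:
    """Keep iff the alt-allele ratio exceeds ``min_ratio`` with posterior support.

    Under a Beta(1,1) prior the posterior of the allele ratio given
    ``k`` alt reads out of ``n`` is Beta(1+k, 1+n-k); the site is kept iff
    P(ratio > min_ratio | k, n) > ``credibility``.
    """
    k, n = site.dep_alt, site.depth
    if n == 0 or k == 0:
        return False
    exceed = stats.beta.sf(min_ratio, 1 + k, 1 + n - k)
    return bool(exceed > credibility)


def filter_strand_bias(site: PlasmaSite, p_threshold: float = 1e-4) -> bool:
    """Keep unless the ref/alt x fwd/rev Fisher exact test rejects at ``p_threshold``.

    Sites without strand counts pass with a warning (filter inapplicable).
    """
    if not site.has_strand:
        logger.warning("%s:%d: no strand counts; strand-bias filter skipped", site.chrom, site.pos)
        return True
    table = [[site.fwd_ref, site.rev_ref], [site.fwd_alt, site.rev_alt]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return bool(p >= p_threshold)


def filter_position_bias(site: PlasmaSite, p_threshold: float = 1e-6) -> bool:
    """Keep unless ref vs alt in-read positions differ by a KS test at ``p_threshold``.

    Sites without position lists, or with fewer than 2 observations in
    either group, pass with a warning (underpowered).
    """
    ref, alt = site.read_positions_ref, site.read_positions_alt
    if ref is None or alt is None:
        logger.warning("%s:%d: no read positions; location-bias filter skipped", site.chrom, site.pos)
        return True
    if len(ref) < 2 or len(alt) < 2:
        logger.warning("%s:%d: <2 read positions per allele; location-bias filter skipped", site.chrom, site.pos)
        return True
    res = stats.ks_2samp(ref, alt)
    return bool(res.pvalue >= p_threshold)


def apply_filters(sites: list[PlasmaSite], config: FilterConfig = FilterConfig()) -> list[FilterResult]:
    """Run every filter on every site; a site is dropped iff any predicate drops it."""
    results = []
    for site in sites:
        failed = []
        if not filter_depth(site, config.min_depth):
            failed.append("depth")
        if config.allele_ratio_enabled and not filter_allele_ratio(
            site, config.min_allele_ratio, config.ratio_credibility
        ):
            failed.append("allele_ratio")
        if not filter_strand_bias(site, config.strand_bias_p):
            failed.append("strand_bias")
        if not filter_position_bias(site, config.position_bias_p):
            failed.append("position_bias")
        results.append(FilterResult(site=site, failed=failed))
    n_drop = sum(not r.keep for r in results)
    if n_drop:
        logger.info("filters dropped %d/%d plasma sites", n_drop, len(sites))
    return results
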
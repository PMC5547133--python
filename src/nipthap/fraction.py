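"""Cell-free fetal DNA fraction estimation from maternal plasma counts.

At SNPs where the parents are homozygous for different alleles the fetus is
an obligate heterozygote, so the paternal-specific allele in plasma comes
only from fetal DNA and its read fraction is f/2.  The fetal fraction is

    f = (1/n) * sum_i 2 * p_i / (p_i + q_i)

where ``p_i`` counts reads of the paternal-specific allele, ``q_i`` reads of
the maternal allele, and ``n`` the number of sites entering the sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from nipthap.filters import PlasmaSite
from nipthap.phasing import InfoClass, PhasedPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionSite:
    """Plasma counts at an opposite-homozygote SNP.

    ``p_count`` is the number of reads supporting the paternal-specific
    allele, ``q_count`` the number supporting the maternal allele.
    """

    pos: int
    p_count: int
    q_count: int

    def __post_init__(self) -> None:
        if self.p_count < 0 or self.q_count < 0:
            raise ValueError(f"negative counts at pos {self.pos}")


@dataclass
class FetalFractionEstimate:
    """Fetal fraction ``f`` (proportion in [0, 1]) with per-site detail."""

    f: float
    n_sites: int
    per_site_f: list[float]

    def percent(self) -> str:
        return f"{100.0 * self.f:.2f}%"


def estimate_fetal_fraction(
    sites: list[FractionSite],
    error_rate: float | None = None,
) -> FetalFractionEstimate:
    """Estimate the fetal DNA fraction from opposite-homozygote sites.

    Parameters
    ----------
    sites
        Sites where the father and mother are homozygous for different
        alleles (selection is the caller's responsibility; see
        :func:`select_fraction_sites`).  Zero-depth sites are excluded with
        a warning.
    error_rate
        Optional per-base sequencing error rate.  When given, the raw
        estimate is inverted through the uniform-substitution error model
        (a read from either allele is misread as the specific other allele
        with probability ``error_rate/3``), removing the upward bias that
        background error adds to the paternal-specific allele count.
        Default ``None`` applies the formula verbatim.

    Raises
    ------
    ValueError
        If no usable site remains.
    """
    per_site: list[float] = []
    n_zero = 0
    for s in sites:
        tot = s.p_count + s.q_count
        if tot == 0:
            n_zero += 1
            continue
        per_site.append(2.0 * s.p_count / tot)
    if n_zero:
        logger.warning("excluded %d zero-depth fetal-fraction sites", n_zero)
    if not per_site:
        raise ValueError("no usable sites: cannot estimate fetal fraction")
    f = sum(per_site) / len(per_site)
    if error_rate is not None:
        from nipthap.hmm import inverse_observed_fraction

        f = 2.0 * inverse_observed_fraction(f / 2.0, error_rate)
    if f > 1.0:
        logger.warning("fetal fraction estimate %.4f > 1 clipped to 1", f)
        f = 1.0
    f = max(f, 0.0)
    return FetalFractionEstimate(f=f, n_sites=len(per_site), per_site_f=per_site)


def select_fraction_sites(panel: PhasedPanel, plasma_by_pos: dict[int, PlasmaSite]) -> list[FractionSite]:
    """Select opposite-homozygote sites and orient their plasma counts.

    For each panel site where both parents are homozygous for different
    alleles and plasma counts are available, the read count of the father's
    allele becomes ``p_count`` (paternal-specific) and the mother's allele
    count becomes ``q_count``.
    """
    out: list[FractionSite] = []
    for i, site in enumerate(panel.sites):
        if panel.info_class[i] != InfoClass.UNINFORMATIVE:
            continue
        fgt, mgt = site.father_gt, site.mother_gt
        if fgt[0] != fgt[1] or mgt[0] != mgt[1] or fgt[0] == mgt[0]:
            continue
        plasma = plasma_by_pos.get(site.pos)
        if plasma is None:
            continue
        pat_allele = fgt[0]
        if pat_allele == site.ref_allele:
            p, q = plasma.dep_ref, plasma.dep_alt
        else:
            p, q = plasma.dep_alt, plasma.dep_ref
        out.append(FractionSite(pos=site.pos, p_count=p, q_count=q))
    return out
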
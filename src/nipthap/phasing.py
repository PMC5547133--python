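"""Trio-based parental haplotype phasing by Mendelian segregation.

Parental haplotypes are reconstructed from father/mother/child genotypes at
biallelic SNPs: at every site where the pair of transmitted alleles is
uniquely determined by Mendel's law of segregation, the allele the child
received from a parent is assigned to the haplotype the child carries from
that parent.  Haplotype 0 (Hap 0) of each parent is defined as the haplotype
linked to that parent's pathogenic allele, anchored by an explicit
``ProbandCarries`` annotation stating whether the proband inherited the
pathogenic haplotype from each parent.

Informative SNPs are the sites whose distinguishing allele occurs on exactly
one of the four parental haplotypes: *paternal-informative* sites have a
heterozygous father and a homozygous mother, *maternal-informative* sites the
reverse.  Only informative sites contribute to downstream haplotype dosage
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger(__name__)

Genotype = tuple[str, str]


class InfoClass(str, Enum):
    """Informativeness of a phased SNP for haplotype dosage analysis."""

    PATERNAL = "paternal_informative"
    MATERNAL = "maternal_informative"
    UNINFORMATIVE = "uninformative"
    UNPHASABLE = "unphasable"


@dataclass(frozen=True)
class TrioSite:
    """One biallelic SNP with unphased father/mother/child genotypes.

    Genotypes are unordered pairs of allele strings drawn from
    ``{ref_allele, alt_allele}``; positions are 1-based (VCF convention).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    father_gt: Genotype
    mother_gt: Genotype
    child_gt: Genotype

    def __post_init__(self) -> None:
        alleles = {self.ref_allele, self.alt_allele}
        for name in ("father_gt", "mother_gt", "child_gt"):
            gt = getattr(self, name)
            if not set(gt) <= alleles:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: {name}={gt} contains alleles "
                    f"outside {{ref={self.ref_allele}, alt={self.alt_allele}}}"
                )


@dataclass(frozen=True)
class ProbandCarries:
    """Which parental pathogenic haplotypes the proband inherited.

    ``paternal=True`` means the proband carries the father's pathogenic
    allele, so the paternal allele transmitted to the proband defines
    paternal Hap 0; ``False`` assigns it to Hap 1 (the complementary
    labelling used for an unaffected proband).
    """

    paternal: bool = True
    maternal: bool = True


@dataclass
class PhasedPanel:
    """Parental haplotypes over an ordered panel of phased trio sites.

    ``paternal_hap0[i]`` etc. hold the allele carried by each haplotype at
    ``sites[i]``; they are ``None`` at unphasable sites.  Hap 0 is the
    pathogenic-linked haplotype of each parent.
    """

    sites: list[TrioSite]
    paternal_hap0: list[str | None]
    paternal_hap1: list[str | None]
    maternal_hap0: list[str | None]
    maternal_hap1: list[str | None]
    info_class: list[InfoClass]
    n_mendelian_errors: int = 0
    mendelian_error_sites: list[TrioSite] = field(default_factory=list)

    def class_counts(self) -> dict[InfoClass, int]:
        counts = {c: 0 for c in InfoClass}
        for c in self.info_class:
            counts[c] += 1
        return counts

    @property
    def n_unphasable(self) -> int:
        return self.class_counts()[InfoClass.UNPHASABLE]


def _is_het(gt: Genotype) -> bool:
    return gt[0] != gt[1]


def classify_informative(site: TrioSite) -> InfoClass:
    """Classify a phased site by which parent it can inform on.

    A site is paternal-informative iff the father is heterozygous and the
    mother homozygous (the father's allele absent from the mother is then
    unique to one paternal haplotype), and symmetrically for
    maternal-informative sites.  Sites where both parents are heterozygous
    or both homozygous distinguish no single haplotype.
    """
    for name in ("father_gt", "mother_gt"):
        if len(getattr(site, name)) != 2:  # defensive; tuples are validated
            logger.warning("%s:%d missing %s; treated as uninformative", site.chrom, site.pos, name)
            return InfoClass.UNINFORMATIVE
    fa_het, mo_het = _is_het(site.father_gt), _is_het(site.mother_gt)
    if fa_het and not mo_het:
        return InfoClass.PATERNAL
    if mo_het and not fa_het:
        return InfoClass.MATERNAL
    return InfoClass.UNINFORMATIVE


def _transmitted_alleles(site: TrioSite) -> set[tuple[str, str]]:
    """All (paternal, maternal) transmissions consistent with the child."""
    child = tuple(sorted(site.child_gt))
    out = set()
    for pa in set(site.father_gt):
        for ma in set(site.mother_gt):
            if tuple(sorted((pa, ma))) == child:
                out.add((pa, ma))
    return out


def _other_allele(gt: Genotype, allele: str) -> str:
    """The allele of ``gt`` complementary to ``allele`` (multiset removal)."""
    g = list(gt)
    g.remove(allele)
    return g[0]


def phase_trio(sites: list[TrioSite], proband_carries: ProbandCarries = ProbandCarries()) -> PhasedPanel:
    """Phase parental haplotypes over ``sites`` and classify informativeness.

    Parameters
    ----------
    sites
        Trio sites sorted by strictly increasing position.
    proband_carries
        Per-parent annotation linking the proband-transmitted haplotype to
        the pathogenic allele; defines Hap 0 of each parent.

    Returns
    -------
    PhasedPanel
        Phased haplotypes, per-site informativeness class, and counts of
        Mendelian-inconsistent sites (excluded with a warning).  Sites where
        the transmission is underdetermined (both parents and the child
        heterozygous) are retained with class ``UNPHASABLE`` and no haplotype
        assignment.

    Raises
    ------
    ValueError
        If ``sites`` is empty or positions are not strictly increasing.
    """
    if not sites:
        raise ValueError("cannot phase an empty site list")
    for a, b in zip(sites, sites[1:]):
        if (a.chrom, a.pos) >= (b.chrom, b.pos):
            raise ValueError(f"sites not sorted by position: {a.chrom}:{a.pos} before {b.chrom}:{b.pos}")

    kept: list[TrioSite] = []
    p0: list[str | None] = []
    p1: list[str | None] = []
    m0: list[str | None] = []
    m1: list[str | None] = []
    classes: list[InfoClass] = []
    mendelian_errors: list[TrioSite] = []

    for site in sites:
        trans = _transmitted_alleles(site)
        if not trans:
            # Mendelian inconsistency: genotyping error or de novo event.
            logger.warning(
                "Mendelian-inconsistent site %s:%d (F=%s M=%s C=%s) excluded",
                site.chrom, site.pos, site.father_gt, site.mother_gt, site.child_gt,
            )
            mendelian_errors.append(site)
            continue
        kept.append(site)
        if len(trans) > 1:
            classes.append(InfoClass.UNPHASABLE)
            p0.append(None); p1.append(None); m0.append(None); m1.append(None)
            continue
        (pa, ma), = trans
        pa_other = _other_allele(site.father_gt, pa)
        ma_other = _other_allele(site.mother_gt, ma)
        if proband_carries.paternal:
            p0.append(pa); p1.append(pa_other)
        else:
            p0.append(pa_other); p1.append(pa)
        if proband_carries.maternal:
            m0.append(ma); m1.append(ma_other)
        else:
            m0.append(ma_other); m1.append(ma)
        classes.append(classify_informative(site))

    if mendelian_errors:
        logger.warning(
            "excluded %d/%d Mendelian-inconsistent sites (%.2f%%)",
            len(mendelian_errors), len(sites), 100.0 * len(mendelian_errors) / len(sites),
        )
    return PhasedPanel(
        sites=kept,
        paternal_hap0=p0,
        paternal_hap1=p1,
        maternal_hap0=m0,
        maternal_hap1=m1,
        info_class=classes,
        n_mendelian_errors=len(mendelian_errors),
        mendelian_error_sites=mendelian_errors,
    )
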
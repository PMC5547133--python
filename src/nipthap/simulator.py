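"""Synthetic trios, fetal inheritance, and plasma counts for method validation.

The generator emulates the targeted-capture study design the method was
validated on: a panel of ~1,607 highly heterozygous SNPs in a 2 Mbp window
around the disease gene, trio genotypes for phasing, fetal inheritance with
recombination drawn from a genetic map, and maternal plasma allele counts
as a binomial mixture of maternal DNA (fraction 1-f) and fetal DNA
(fraction f) at Poisson-distributed depth with uniform-substitution
sequencing error.  Depth downsampling reproduces the read-subsampling
protocol used to probe the method's detection limits.

Because the capture panel is ascertained for heterozygosity in the tested
families, each site's informativeness class is drawn directly (defaults:
44% paternal-informative, 46% maternal-informative, 4% opposite-homozygote
for fetal-fraction estimation, 6% other), matching the informative-site
counts reported for real families rather than Hardy-Weinberg proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nipthap.filters import PlasmaSite
from nipthap.fraction import FractionSite
from nipthap.phasing import TrioSite

_BASES = np.array(list("ACGT"))

# informativeness classes
_PAT, _MAT, _OPP_HOM, _OTHER = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic family and plasma sample."""

    n_snps: int = 1607
    region_span: int = 2_000_000
    chrom: str = "6"
    maf_range: tuple[float, float] = (0.3, 0.5)
    f: float = 0.10
    mean_depth: float = 200.0
    error_rate: float = 0.005
    recomb_rate_cm_per_mb: float = 1.0
    class_weights: tuple[float, float, float, float] = (0.44, 0.46, 0.04, 0.06)
    gene_span: int = 3_400
    proband_carries_paternal: bool = True
    proband_carries_maternal: bool = True
    fetal_pat_hap: int | None = None      # None: drawn uniformly
    fetal_mat_hap: int | None = None
    crossovers_pat: tuple[int, ...] | None = None  # forced positions (bp)
    crossovers_mat: tuple[int, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 10:
            raise ValueError("n_snps must be at least 10")
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"fetal fraction {self.f} outside [0, 1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error rate {self.error_rate} outside [0, 0.5)")
        if abs(sum(self.class_weights) - 1.0) > 1e-9 or min(self.class_weights) < 0:
            raise ValueError("class_weights must be a probability vector")

    @property
    def gene_interval(self) -> tuple[int, int]:
        mid = self.region_span // 2
        return (mid - self.gene_span // 2, mid + self.gene_span // 2)


@dataclass
class SimulatedFamily:
    """Ground truth of one simulated trio + fetus."""

    config: SimConfig
    positions: np.ndarray             # 1-based, strictly increasing
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray
    father_haps: np.ndarray           # (2, n) of 0/1; row 0 = pathogenic-linked Hap 0
    mother_haps: np.ndarray
    site_class: np.ndarray            # _PAT/_MAT/_OPP_HOM/_OTHER per site
    fetal_pat_hap_at_site: np.ndarray  # (n,) transmitted paternal hap index
    fetal_mat_hap_at_site: np.ndarray
    crossovers_pat: np.ndarray        # bp positions
    crossovers_mat: np.ndarray
    truth_pat_hap: int = 0            # transmitted hap index at the gene locus
    truth_mat_hap: int = 0

    def _letters(self, code: np.ndarray) -> np.ndarray:
        return np.where(code == 0, self.ref_alleles, self.alt_alleles)

    def trio_sites(self) -> list[TrioSite]:
        """Materialise the trio genotypes as :class:`TrioSite` records."""
        cfg = self.config
        pp = 0 if cfg.proband_carries_paternal else 1
        pm = 0 if cfg.proband_carries_maternal else 1
        f0 = self._letters(self.father_haps[0])
        f1 = self._letters(self.father_haps[1])
        m0 = self._letters(self.mother_haps[0])
        m1 = self._letters(self.mother_haps[1])
        child_p = f0 if pp == 0 else f1
        child_m = m0 if pm == 0 else m1
        return [
            TrioSite(
                chrom=cfg.chrom,
                pos=int(self.positions[i]),
                ref_allele=str(self.ref_alleles[i]),
                alt_allele=str(self.alt_alleles[i]),
                father_gt=(str(f0[i]), str(f1[i])),
                mother_gt=(str(m0[i]), str(m1[i])),
                child_gt=(str(child_p[i]), str(child_m[i])),
            )
            for i in range(len(self.positions))
        ]

    def fetal_alt_dosage(self) -> np.ndarray:
        n = len(self.positions)
        idx = np.arange(n)
        return (
            self.father_haps[self.fetal_pat_hap_at_site, idx]
            + self.mother_haps[self.fetal_mat_hap_at_site, idx]
        )

    def maternal_alt_dosage(self) -> np.ndarray:
        return self.mother_haps.sum(axis=0)


def _transmitted_hap(start: int, crossovers: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Hap index at each position of a gamete starting in ``start`` with
    crossovers at the given bp coordinates."""
    n_before = np.searchsorted(np.sort(crossovers), positions)
    return (start + n_before) % 2


def simulate_family(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedFamily:
    """Draw a trio, its haplotypes and the fetus's transmitted haplotypes.

    Hap 0 of each parent is the pathogenic-linked haplotype; the proband
    inherits it according to ``cfg.proband_carries_*``.  The fetal gamete of
    each parent starts on a (configured or uniformly drawn) haplotype and
    switches at crossover positions drawn from a Poisson process on the
    genetic map (``recomb_rate_cm_per_mb``) unless forced positions are
    given.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, span = cfg.n_snps, cfg.region_span

    positions = np.sort(rng.choice(span, size=n, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ref_alleles = _BASES[ref_idx]
    alt_alleles = _BASES[alt_idx]

    site_class = rng.choice(4, size=n, p=cfg.class_weights)
    p_alt = rng.uniform(*cfg.maf_range, size=n)
    hom_pick = (rng.random(n) < p_alt).astype(np.int8)       # hom-parent allele
    flip_f = rng.integers(0, 2, size=n).astype(np.int8)      # het placement on hap0/hap1
    flip_m = rng.integers(0, 2, size=n).astype(np.int8)
    hom_same = (rng.random(n) < p_alt).astype(np.int8)       # "other" class hom allele
    other_het = rng.random(n) < 0.5

    father = np.empty((2, n), dtype=np.int8)
    mother = np.empty((2, n), dtype=np.int8)

    pat = site_class == _PAT
    father[0, pat] = flip_f[pat]
    father[1, pat] = 1 - flip_f[pat]
    mother[0, pat] = mother[1, pat] = hom_pick[pat]

    mat = site_class == _MAT
    mother[0, mat] = flip_m[mat]
    mother[1, mat] = 1 - flip_m[mat]
    father[0, mat] = father[1, mat] = hom_pick[mat]

    opp = site_class == _OPP_HOM
    father[0, opp] = father[1, opp] = hom_pick[opp]
    mother[0, opp] = mother[1, opp] = 1 - hom_pick[opp]

    oth = site_class == _OTHER
    both_het = oth & other_het
    father[0, both_het] = flip_f[both_het]
    father[1, both_het] = 1 - flip_f[both_het]
    mother[0, both_het] = flip_m[both_het]
    mother[1, both_het] = 1 - flip_m[both_het]
    both_hom = oth & ~other_het
    father[0, both_hom] = father[1, both_hom] = hom_same[both_hom]
    mother[0, both_hom] = mother[1, both_hom] = hom_same[both_hom]

    l_morgan = span * cfg.recomb_rate_cm_per_mb / 1e6 / 100.0

    def gamete(forced: tuple[int, ...] | None, start_cfg: int | None):
        if forced is not None:
            xo = np.asarray(forced, dtype=float)
        else:
            xo = rng.uniform(0, span, size=rng.poisson(l_morgan))
        start = int(rng.integers(0, 2)) if start_cfg is None else int(start_cfg)
        return start, np.sort(xo)

    pat_start, xo_pat = gamete(cfg.crossovers_pat, cfg.fetal_pat_hap)
    mat_start, xo_mat = gamete(cfg.crossovers_mat, cfg.fetal_mat_hap)
    fetal_pat = _transmitted_hap(pat_start, xo_pat, positions)
    fetal_mat = _transmitted_hap(mat_start, xo_mat, positions)
    gene_mid = sum(cfg.gene_interval) / 2.0
    truth_pat = int(_transmitted_hap(pat_start, xo_pat, np.array([gene_mid]))[0])
    truth_mat = int(_transmitted_hap(mat_start, xo_mat, np.array([gene_mid]))[0])

    return SimulatedFamily(
        config=cfg,
        positions=positions,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
        father_haps=father,
        mother_haps=mother,
        site_class=site_class,
        fetal_pat_hap_at_site=fetal_pat,
        fetal_mat_hap_at_site=fetal_mat,
        crossovers_pat=xo_pat,
        crossovers_mat=xo_mat,
        truth_pat_hap=truth_pat,
        truth_mat_hap=truth_mat,
    )


def _sequencing_error(rng: np.random.Generator, alt_true: np.ndarray, ref_true: np.ndarray,
                      error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-substitution error: each read is misread to each of the three
    other bases with probability error_rate/3; reads landing on neither
    allele of the pair are dropped from the counts."""
    e = error_rate
    alt_kept = rng.binomial(alt_true, 1.0 - e)
    alt_to_ref = rng.binomial(alt_true - alt_kept, 1.0 / 3.0)
    ref_kept = rng.binomial(ref_true, 1.0 - e)
    ref_to_alt = rng.binomial(ref_true - ref_kept, 1.0 / 3.0)
    return ref_kept + alt_to_ref, alt_kept + ref_to_alt


def simulate_plasma(
    family: SimulatedFamily,
    rng: np.random.Generator | None = None,
    include_strand: bool = True,
    include_read_positions: bool = False,
    read_length: int = 101,
    strand_bias_at: frozenset[int] = frozenset(),
    position_bias_at: frozenset[int] = frozenset(),
    fixed_depth: bool = False,
) -> list[PlasmaSite]:
    """Draw maternal plasma allele counts for a simulated family.

    At each site the true alternate-allele fraction is the mixture
    ``(1-f) * maternal_dosage/2 + f * fetal_dosage/2``; per-site depth is
    Poisson around ``mean_depth`` (or fixed when ``fixed_depth``), and
    sequencing error follows the uniform-substitution model.  Strand counts
    and in-read positions are drawn unbiased unless a site position is
    listed in ``strand_bias_at`` (all alt reads forward) or
    ``position_bias_at`` (alt reads confined to the first 5 bases).
    """
    cfg = family.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(family.positions)
    f = cfg.f
    p_alt = (1.0 - f) * family.maternal_alt_dosage() / 2.0 + f * family.fetal_alt_dosage() / 2.0
    if fixed_depth:
        depth = np.full(n, int(round(cfg.mean_depth)))
    else:
        depth = rng.poisson(cfg.mean_depth, size=n)
    alt_true = rng.binomial(depth, p_alt)
    ref_true = depth - alt_true
    dep_ref, dep_alt = _sequencing_error(rng, alt_true, ref_true, cfg.error_rate)

    if include_strand:
        fwd_ref = rng.binomial(dep_ref, 0.5)
        fwd_alt = rng.binomial(dep_alt, 0.5)
    sites: list[PlasmaSite] = []
    for i in range(n):
        pos = int(family.positions[i])
        kw: dict = {}
        if include_strand:
            fa = int(dep_alt[i]) if pos in strand_bias_at else int(fwd_alt[i])
            kw.update(
                fwd_ref=int(fwd_ref[i]), rev_ref=int(dep_ref[i] - fwd_ref[i]),
                fwd_alt=fa, rev_alt=int(dep_alt[i] - fa),
            )
        if include_read_positions:
            ref_pos = rng.integers(0, read_length, size=int(dep_ref[i]))
            if pos in position_bias_at:
                alt_pos = rng.integers(0, 5, size=int(dep_alt[i]))
            else:
                alt_pos = rng.integers(0, read_length, size=int(dep_alt[i]))
            kw.update(
                read_positions_ref=tuple(int(x) for x in ref_pos),
                read_positions_alt=tuple(int(x) for x in alt_pos),
            )
        sites.append(PlasmaSite(
            chrom=cfg.chrom, pos=pos, dep_ref=int(dep_ref[i]), dep_alt=int(dep_alt[i]), **kw,
        ))
    return sites


def downsample(
    plasma: list[PlasmaSite],
    target_mean_depth: float,
    rng: np.random.Generator | int | None,
) -> list[PlasmaSite]:
    """Thin plasma counts to a target mean depth by binomial subsampling.

    Each count is thinned independently with retention probability
    ``target / current_mean``, which preserves allele-ratio expectations;
    thinned counts never exceed the originals.  A target equal to the
    current mean returns the sites unchanged.
    """
    if isinstance(rng, int) or rng is None:
        rng = np.random.default_rng(rng)
    current = float(np.mean([s.depth for s in plasma]))
    if target_mean_depth > current:
        raise ValueError(f"target depth {target_mean_depth} exceeds current mean {current:.2f}")
    if target_mean_depth == current:
        return list(plasma)
    r = target_mean_depth / current

    def thin(count: int) -> int:
        return int(rng.binomial(count, r))

    out: list[PlasmaSite] = []
    for s in plasma:
        kw: dict = {}
        if s.has_strand:
            fr, rr = thin(s.fwd_ref), thin(s.rev_ref)
            fa, ra = thin(s.fwd_alt), thin(s.rev_alt)
            dep_ref, dep_alt = fr + rr, fa + ra
            kw.update(fwd_ref=fr, rev_ref=rr, fwd_alt=fa, rev_alt=ra)
        else:
            dep_ref, dep_alt = thin(s.dep_ref), thin(s.dep_alt)
        if s.read_positions_ref is not None:
            keep_r = rng.choice(len(s.read_positions_ref), size=dep_ref, replace=False) \
                if dep_ref <= len(s.read_positions_ref) else np.arange(len(s.read_positions_ref))
            keep_a = rng.choice(len(s.read_positions_alt), size=dep_alt, replace=False) \
                if dep_alt <= len(s.read_positions_alt) else np.arange(len(s.read_positions_alt))
            kw.update(
                read_positions_ref=tuple(s.read_positions_ref[i] for i in sorted(keep_r)),
                read_positions_alt=tuple(s.read_positions_alt[i] for i in sorted(keep_a)),
            )
        out.append(PlasmaSite(chrom=s.chrom, pos=s.pos, dep_ref=dep_ref, dep_alt=dep_alt, **kw))
    return out


def simulate_y_depths(
    fetal_sex: str,
    rng: np.random.Generator,
    n_bases: int = 13_300,
    male_mean_depth: float = 60.0,
    female_mean_depth: float = 1.0,
) -> np.ndarray:
    """Per-base depths over a stand-in Y-specific capture target.

    A male fetus contributes captured chrY fragments (deep, near-complete
    coverage); in a female pregnancy only non-specific mapping noise
    remains.  The region itself is synthetic: the real probe coordinates
    are not modelled, only the coverage signal the sex caller consumes.
    """
    mean = male_mean_depth if fetal_sex == "male" else female_mean_depth
    return rng.poisson(mean, size=n_bases).astype(float)


def simulate_fraction_sites(
    n_sites: int,
    f: float,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> list[FractionSite]:
    """Plasma counts at opposite-homozygote sites (fetus obligate het).

    The paternal-specific allele's true fraction is f/2; counts include the
    uniform-substitution sequencing error.
    """
    depth = rng.poisson(mean_depth, size=n_sites)
    p_true = rng.binomial(depth, f / 2.0)
    q_true = depth - p_true
    q_obs, p_obs = _sequencing_error(rng, p_true, q_true, error_rate)
    return [
        FractionSite(pos=i + 1, p_count=int(p_obs[i]), q_count=int(q_obs[i]))
        for i in range(n_sites)
    ]
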
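"""Two-state HMM for fetal haplotype inheritance from plasma allele counts.

Hidden states are the two haplotypes a parent can transmit to the fetus,
``Q = {Hap 0, Hap 1}`` (Hap 0 carries the pathogenic allele), with initial
distribution ``pi = (1/2, 1/2)``.  At informative SNP ``j`` the observation
is ``k`` reads of the haplotype-distinguishing allele out of ``n`` total;
its likelihood under state ``i`` is the binomial ``b(k, n, prob_i)`` where
``prob_i`` is the expected plasma fraction of that allele when the fetus
inherits Hap ``i``:

* paternal-informative site (father heterozygous, mother homozygous): the
  informative allele is fetal-specific, so its fraction is f/2 when the
  fetus carries the haplotype bearing it, and ~0 (sequencing error floor)
  otherwise;
* maternal-informative site (mother heterozygous, father homozygous): the
  informative maternal allele sits at 1/2 when transmitted and (1-f)/2
  when not — the relative haplotype dosage imbalance of size f/2.

Between neighbouring SNPs the state switches with the recombination
probability given by the genetic distance through the Haldane map function.
The most probable state path is found by max-product Viterbi in log space,
and the cumulative log-odds of Hap 0 versus Hap 1 transmission is reported
per site for plotting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from nipthap.filters import PlasmaSite
from nipthap.phasing import InfoClass, PhasedPanel

logger = logging.getLogger(__name__)

HAP0, HAP1 = 0, 1

#: Floor / cap on the per-interval recombination probability.
RECOMB_FLOOR = 1e-6
RECOMB_CAP = 0.5


def observed_fraction(p_true: float, error_rate: float) -> float:
    """Expected counted fraction of an allele under uniform substitution error.

    A read from either allele is misread as each of the three other bases
    with probability ``error_rate/3``; reads showing neither allele of the
    pair are not counted, hence the renormalisation.
    """
    e = error_rate
    return (p_true * (1.0 - e) + (1.0 - p_true) * e / 3.0) / (1.0 - 2.0 * e / 3.0)


def inverse_observed_fraction(p_obs: float, error_rate: float) -> float:
    """Invert :func:`observed_fraction`; clipped to [0, 1]."""
    e = error_rate
    p = (p_obs * (1.0 - 2.0 * e / 3.0) - e / 3.0) / (1.0 - 4.0 * e / 3.0)
    return min(max(p, 0.0), 1.0)


def expected_proportions(
    info_class: InfoClass,
    informative_on_hap0: bool,
    f: float,
    error_rate: float = 0.005,
) -> tuple[float, float]:
    """Expected informative-allele fractions (prob0, prob1) under each state.

    Parameters
    ----------
    info_class
        ``PATERNAL`` or ``MATERNAL`` informativeness of the site.
    informative_on_hap0
        Whether the distinguishing allele lies on the parent's Hap 0.
    f
        Fetal DNA fraction, in [0, 1).
    error_rate
        Per-base sequencing error (uniform substitution model).
    """
    if not 0.0 <= f < 1.0:
        raise ValueError(f"fetal fraction f={f} outside [0, 1)")
    if info_class == InfoClass.PATERNAL:
        p_carry, p_other = f / 2.0, 0.0
    elif info_class == InfoClass.MATERNAL:
        p_carry, p_other = 0.5, (1.0 - f) / 2.0
    else:
        raise ValueError(f"site class {info_class} has no emission model")
    p_carry = observed_fraction(p_carry, error_rate)
    p_other = observed_fraction(p_other, error_rate)
    return (p_carry, p_other) if informative_on_hap0 else (p_other, p_carry)


@dataclass(frozen=True)
class ObservedSite:
    """Plasma observation at one informative SNP.

    ``k`` counts reads of the Hap-0/Hap-1 distinguishing allele, ``n_reads``
    all counted reads at the site.
    """

    pos: int
    info_class: InfoClass
    informative_on_hap0: bool
    k: int
    n_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n_reads:
            raise ValueError(f"pos {self.pos}: k={self.k} outside [0, n={self.n_reads}]")


@dataclass
class EmissionModel:
    """Binomial emission model at fetal fraction ``f``."""

    f: float
    error_rate: float = 0.005

    def site_proportions(self, site: ObservedSite) -> tuple[float, float]:
        return expected_proportions(site.info_class, site.informative_on_hap0, self.f, self.error_rate)

    def log_likelihoods(self, sites: list[ObservedSite]) -> np.ndarray:
        """(n_sites, 2) array of log P{N_j | Hap i}."""
        k = np.array([s.k for s in sites])
        n = np.array([s.n_reads for s in sites])
        probs = np.array([self.site_proportions(s) for s in sites])  # (n, 2)
        return stats.binom.logpmf(k[:, None], n[:, None], probs)


def emission_posterior(site: ObservedSite, model: EmissionModel) -> tuple[float, float]:
    """Posterior P{Hap i | N_j} with equal priors, normalised to sum to 1.

    Both binomial likelihoods are evaluated in log space and combined with
    a log-sum-exp normalisation; if both vanish the posterior is (1/2, 1/2).
    """
    if site.n_reads == 0:
        logger.warning("pos %d: zero depth; uninformative posterior", site.pos)
        return (0.5, 0.5)
    ll = model.log_likelihoods([site])[0]
    if np.all(np.isinf(ll)):
        return (0.5, 0.5)
    post = np.exp(ll - logsumexp(ll))
    return (float(post[0]), float(post[1]))


class GeneticMap:
    """Cumulative genetic position (cM) along a chromosome.

    Either a constant rate (cM/Mb) or a 3-column table (chrom, pos, cM)
    interpolated linearly between map points and extrapolated at the ends
    with the flanking interval's rate.
    """

    def __init__(self, positions_bp: np.ndarray | None = None, cm: np.ndarray | None = None,
                 rate_cm_per_mb: float = 1.0):
        if (positions_bp is None) != (cm is None):
            raise ValueError("positions_bp and cm must be given together")
        if positions_bp is not None:
            positions_bp = np.asarray(positions_bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if positions_bp.size < 2 or np.any(np.diff(positions_bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValueError("genetic map must have >=2 points, increasing pos and nondecreasing cM")
        self._pos = positions_bp
        self._cm = cm
        self.rate_cm_per_mb = rate_cm_per_mb

    @classmethod
    def constant(cls, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(rate_cm_per_mb=rate_cm_per_mb)

    @classmethod
    def from_table(cls, positions_bp, cm) -> "GeneticMap":
        return cls(positions_bp=np.asarray(positions_bp), cm=np.asarray(cm))

    def cm_at(self, pos: float) -> float:
        if self._pos is None:
            return pos * self.rate_cm_per_mb / 1e6
        # linear interpolation with end-interval extrapolation
        p, c = self._pos, self._cm
        if pos <= p[0]:
            rate = (c[1] - c[0]) / (p[1] - p[0])
            return float(c[0] + (pos - p[0]) * rate)
        if pos >= p[-1]:
            rate = (c[-1] - c[-2]) / (p[-1] - p[-2])
            return float(c[-1] + (pos - p[-1]) * rate)
        return float(np.interp(pos, p, c))

    def genetic_distance_morgan(self, pos_a: float, pos_b: float) -> float:
        return abs(self.cm_at(pos_b) - self.cm_at(pos_a)) / 100.0


def recombination_probability(d_morgan: float) -> float:
    """Haldane map function P = (1 - exp(-2d)) / 2, floored and capped."""
    p = 0.5 * (1.0 - math.exp(-2.0 * d_morgan))
    return min(max(p, RECOMB_FLOOR), RECOMB_CAP)


def transition_matrix(pos_a: int, pos_b: int, genetic_map: GeneticMap) -> np.ndarray:
    """2x2 transition matrix between neighbouring SNPs at ``pos_a < pos_b``."""
    if pos_a >= pos_b:
        raise ValueError(f"positions out of order: {pos_a} >= {pos_b}")
    p = recombination_probability(genetic_map.genetic_distance_morgan(pos_a, pos_b))
    return np.array([[1.0 - p, p], [p, 1.0 - p]])


@dataclass
class HMMResult:
    """Viterbi decoding of one parental chain."""

    parent: str
    positions: np.ndarray
    path: np.ndarray                  # per-site state, 0 = Hap0, 1 = Hap1
    log_odds: np.ndarray              # cumulative log-odds of Hap0 vs Hap1
    emission_log_odds: np.ndarray     # cumulative emission-only evidence
    n_recombinations: int
    transmitted_hap: int | None = None  # state at the target-gene locus
    n_sites_skipped: int = 0

    @property
    def transmitted_label(self) -> str | None:
        if self.transmitted_hap is None:
            return None
        return f"Hap{self.transmitted_hap}"


def viterbi(
    log_emissions: np.ndarray,
    log_transitions: np.ndarray,
    positions: np.ndarray | None = None,
    parent: str = "",
) -> HMMResult:
    """Max-product Viterbi decoding of a two-state chain in log space.

    Parameters
    ----------
    log_emissions
        (n, 2) per-site log-likelihoods of the observation under Hap0/Hap1.
    log_transitions
        (n-1, 2, 2) per-interval log transition matrices.
    positions
        Optional site coordinates carried through to the result.

    Ties are broken toward staying in the previous state (no recombination);
    a tie in the terminal score resolves to Hap 0.
    """
    b = np.asarray(log_emissions, dtype=float)
    n = b.shape[0]
    if n == 0:
        raise ValueError("no informative sites: no call possible")
    a = np.asarray(log_transitions, dtype=float).reshape(max(n - 1, 0), 2, 2)
    if a.shape[0] != n - 1:
        raise ValueError(f"need {n - 1} transition matrices, got {a.shape[0]}")

    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=np.int8)
    delta[0] = math.log(0.5) + b[0]
    for j in range(1, n):
        for s in (0, 1):
            stay = delta[j - 1, s] + a[j - 1, s, s]
            switch = delta[j - 1, 1 - s] + a[j - 1, 1 - s, s]
            if switch > stay:
                delta[j, s] = switch + b[j, s]
                psi[j, s] = 1 - s
            else:
                delta[j, s] = stay + b[j, s]
                psi[j, s] = s

    path = np.empty(n, dtype=np.int8)
    path[-1] = HAP0 if delta[-1, HAP0] >= delta[-1, HAP1] else HAP1
    for j in range(n - 1, 0, -1):
        path[j - 1] = psi[j, path[j]]

    log_odds = delta[:, HAP0] - delta[:, HAP1]
    n_rec = int(np.sum(path[1:] != path[:-1]))
    if positions is None:
        positions = np.arange(n)
    return HMMResult(
        parent=parent,
        positions=np.asarray(positions),
        path=path,
        log_odds=log_odds,
        emission_log_odds=np.cumsum(b[:, HAP0] - b[:, HAP1]),
        n_recombinations=n_rec,
    )


def build_observed_sites(
    panel: PhasedPanel,
    plasma_by_pos: dict[int, PlasmaSite],
    parent: str,
    min_depth: int = 1,
) -> list[ObservedSite]:
    """Project panel + plasma onto one parent's informative-site chain.

    ``parent`` is ``"paternal"`` or ``"maternal"``.  The distinguishing
    allele is the heterozygous parent's allele absent from the homozygous
    parent; ``informative_on_hap0`` records which haplotype of the
    heterozygous parent carries it.  Sites without plasma counts or below
    ``min_depth`` are skipped.
    """
    if parent == "paternal":
        want = InfoClass.PATERNAL
        hap0 = panel.paternal_hap0
    elif parent == "maternal":
        want = InfoClass.MATERNAL
        hap0 = panel.maternal_hap0
    else:
        raise ValueError(f"unknown parent {parent!r}")
    out: list[ObservedSite] = []
    n_skipped = 0
    for i, site in enumerate(panel.sites):
        if panel.info_class[i] != want:
            continue
        het_gt = site.father_gt if want is InfoClass.PATERNAL else site.mother_gt
        hom_gt = site.mother_gt if want is InfoClass.PATERNAL else site.father_gt
        info_allele = het_gt[0] if het_gt[0] != hom_gt[0] else het_gt[1]
        plasma = plasma_by_pos.get(site.pos)
        if plasma is None or plasma.depth < max(min_depth, 1):
            n_skipped += 1
            continue
        k = plasma.dep_ref if info_allele == site.ref_allele else plasma.dep_alt
        out.append(ObservedSite(
            pos=site.pos,
            info_class=want,
            informative_on_hap0=(hap0[i] == info_allele),
            k=k,
            n_reads=plasma.depth,
        ))
    if n_skipped:
        logger.info("%s chain: skipped %d informative sites without usable plasma counts", parent, n_skipped)
    return out


def decode_parent(
    sites: list[ObservedSite],
    model: EmissionModel,
    genetic_map: GeneticMap,
    parent: str = "",
) -> HMMResult:
    """Decode one parental chain: emissions, transitions, Viterbi."""
    if not sites:
        raise ValueError(f"{parent or 'parental'} chain has no informative sites")
    log_b = model.log_likelihoods(sites)
    positions = np.array([s.pos for s in sites])
    log_a = np.empty((len(sites) - 1, 2, 2))
    for j in range(len(sites) - 1):
        log_a[j] = np.log(transition_matrix(positions[j], positions[j + 1], genetic_map))
    return viterbi(log_b, log_a, positions=positions, parent=parent)


def state_at_locus(result: HMMResult, gene_start: int, gene_end: int) -> int | None:
    """Viterbi state at the gene interval, from flanking informative sites.

    The states of all sites inside [gene_start, gene_end] plus the nearest
    informative site on each side are collected; a unanimous state is the
    call, disagreement (a recombination at the locus) yields ``None``.
    """
    pos = result.positions
    idx = set(np.nonzero((pos >= gene_start) & (pos <= gene_end))[0].tolist())
    left = np.nonzero(pos < gene_start)[0]
    right = np.nonzero(pos > gene_end)[0]
    if left.size:
        idx.add(int(left[-1]))
    if right.size:
        idx.add(int(right[0]))
    if not idx:
        return None
    states = {int(result.path[i]) for i in idx}
    if len(states) == 1:
        return states.pop()
    return None


@dataclass
class FetalInference:
    """Full HMM inference for both parental chains."""

    paternal: HMMResult
    maternal: HMMResult | None
    paternal_call: str | None        # "P0" / "P1" / None
    maternal_call: str | None        # "M0" / "M1" / None
    f: float
    maternal_refused: bool = False


def infer_fetal_haplotypes(
    panel: PhasedPanel,
    plasma: list[PlasmaSite],
    f: float,
    gene_interval: tuple[int, int],
    genetic_map: GeneticMap | None = None,
    error_rate: float = 0.005,
    f_floor: float = 0.01,
    min_depth: int = 1,
) -> FetalInference:
    """Decode both parental chains and call the transmitted haplotypes.

    The transmitted haplotype reported for the disease locus is the Viterbi
    state at the informative-site interval containing ``gene_interval``.
    When ``f`` is below ``f_floor`` the maternal dosage imbalance (f/2) is
    too small to trust; the maternal chain is still decoded for diagnostics
    but no maternal call is issued.
    """
    if genetic_map is None:
        genetic_map = GeneticMap.constant()
    plasma_by_pos = {s.pos: s for s in plasma}
    model = EmissionModel(f=f, error_rate=error_rate)

    pat_sites = build_observed_sites(panel, plasma_by_pos, "paternal", min_depth)
    pat = decode_parent(pat_sites, model, genetic_map, parent="paternal")
    pat_state = state_at_locus(pat, *gene_interval)
    pat.transmitted_hap = pat_state

    mat_sites = build_observed_sites(panel, plasma_by_pos, "maternal", min_depth)
    mat = decode_parent(mat_sites, model, genetic_map, parent="maternal")
    mat_state = state_at_locus(mat, *gene_interval)
    mat.transmitted_hap = mat_state

    refused = f < f_floor
    if refused:
        logger.warning(
            "fetal fraction %.4f below floor %.4f: maternal haplotype call refused "
            "(dosage imbalance f/2 too small)", f, f_floor,
        )
    return FetalInference(
        paternal=pat,
        maternal=mat,
        paternal_call=None if pat_state is None else f"P{pat_state}",
        maternal_call=None if (refused or mat_state is None) else f"M{mat_state}",
        f=f,
        maternal_refused=refused,
    )
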
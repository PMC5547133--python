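"""Clinical-style fetal genotype/status report composition.

Maps the inferred transmitted haplotypes (P0/P1 x M0/M1) to a fetal
genotype label by substituting each parent's annotated pathogenic or
wild-type allele name, and to a disease status for the autosomal-recessive
locus: affected when both pathogenic-linked haplotypes are transmitted,
carrier when exactly one is, unaffected when neither is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from nipthap.hmm import FetalInference

WILD_TYPE = "WT"


@dataclass(frozen=True)
class ParentalMutations:
    """Pathogenic-allele names carried on each parent's Hap 0."""

    paternal: str
    maternal: str


@dataclass
class FetalCall:
    """Composed noninvasive prenatal diagnosis for one plasma sample."""

    paternal_hap: str | None         # "P0" / "P1" / None
    maternal_hap: str | None
    genotype_label: str | None       # e.g. "Del/WT", paternal allele first
    status: str                      # affected | carrier | unaffected | no-call
    no_call_reason: str | None
    sex: str
    fetal_fraction: float
    n_informative: tuple[int, int]   # (paternal, maternal) site counts

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _status(paternal_hap: str, maternal_hap: str) -> str:
    n_pathogenic = (paternal_hap == "P0") + (maternal_hap == "M0")
    return {2: "affected", 1: "carrier", 0: "unaffected"}[n_pathogenic]


def compose_call(
    inference: FetalInference,
    sex: str,
    mutations: ParentalMutations,
) -> FetalCall:
    """Compose the report from decoded chains, sex call and annotations.

    An indeterminate chain (no-call at the locus, or a refused maternal
    call at low fetal fraction) yields status ``no-call`` with a reason.
    """
    pat, mat = inference.paternal_call, inference.maternal_call
    n_inf = (len(inference.paternal.positions),
             0 if inference.maternal is None else len(inference.maternal.positions))

    reason = None
    if pat is None:
        reason = "paternal haplotype indeterminate at the locus"
    elif mat is None:
        reason = ("fetal fraction below maternal-call floor"
                  if inference.maternal_refused
                  else "maternal haplotype indeterminate at the locus")

    if reason is not None:
        return FetalCall(
            paternal_hap=pat, maternal_hap=mat, genotype_label=None,
            status="no-call", no_call_reason=reason, sex=sex,
            fetal_fraction=inference.f, n_informative=n_inf,
        )
    pat_allele = mutations.paternal if pat == "P0" else WILD_TYPE
    mat_allele = mutations.maternal if mat == "M0" else WILD_TYPE
    return FetalCall(
        paternal_hap=pat, maternal_hap=mat,
        genotype_label=f"{pat_allele}/{mat_allele}",
        status=_status(pat, mat), no_call_reason=None, sex=sex,
        fetal_fraction=inference.f, n_informative=n_inf,
    )
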
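"""Readers, writers and run configuration for the pipeline's file formats.

Interchange formats are deliberately plain: tab-delimited UTF-8 tables with
headers for trio genotypes, phased panels, plasma counts, per-site
log-odds tracks and Y-region depth; VCF 4.x (via cyvcf2) for trio
genotypes; YAML or JSON for run configuration; JSON for the final report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nipthap.filters import PlasmaSite
from nipthap.hmm import HMMResult
from nipthap.phasing import InfoClass, PhasedPanel, TrioSite

logger = logging.getLogger(__name__)

TRIO_COLUMNS = ["chrom", "pos", "ref", "alt", "father_gt", "mother_gt", "child_gt"]
PLASMA_COLUMNS = ["chrom", "pos", "dep_ref", "dep_alt"]
PLASMA_STRAND_COLUMNS = ["fwd_ref", "rev_ref", "fwd_alt", "rev_alt"]
PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "P0", "P1", "M0", "M1", "info_class"]


def _parse_gt(text: str, chrom: str, pos: int, line: int) -> tuple[str, str]:
    parts = text.replace("|", "/").split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"line {line}: malformed genotype {text!r} at {chrom}:{pos}")
    return (parts[0], parts[1])


def read_trio_tsv(path: str | Path) -> list[TrioSite]:
    """Read trio genotypes from a TSV with columns chrom, pos, ref, alt,
    father_gt, mother_gt, child_gt (genotypes like ``A/G``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TRIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pos = int(row.pos)
        sites.append(TrioSite(
            chrom=row.chrom, pos=pos, ref_allele=row.ref, alt_allele=row.alt,
            father_gt=_parse_gt(row.father_gt, row.chrom, pos, i),
            mother_gt=_parse_gt(row.mother_gt, row.chrom, pos, i),
            child_gt=_parse_gt(row.child_gt, row.chrom, pos, i),
        ))
    return sites


def write_trio_tsv(sites: list[TrioSite], path: str | Path) -> None:
    df = pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref_allele for s in sites],
        "alt": [s.alt_allele for s in sites],
        "father_gt": ["/".join(s.father_gt) for s in sites],
        "mother_gt": ["/".join(s.mother_gt) for s in sites],
        "child_gt": ["/".join(s.child_gt) for s in sites],
    })
    df.to_csv(path, sep="\t", index=False)


def read_trio_vcf(path: str | Path, father: str, mother: str, child: str) -> list[TrioSite]:
    """Extract biallelic SNPs for the three named samples from a VCF.

    Multiallelic records, indels and sites with missing genotypes are
    skipped with logged counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        idx = {name: samples.index(name) for name in (father, mother, child)}
    except ValueError as err:
        raise ValueError(f"{path}: sample missing from VCF ({err}); present: {samples}") from None

    sites: list[TrioSite] = []
    n_skipped = {"multiallelic": 0, "indel": 0, "missing_gt": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped["indel"] += 1
            continue
        alleles = (rec.REF, rec.ALT[0])
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        parsed = {}
        ok = True
        for name, i in idx.items():
            a, b = gts[i][0], gts[i][1]
            if a < 0 or b < 0:
                ok = False
                break
            parsed[name] = (alleles[a], alleles[b])
        if not ok:
            n_skipped["missing_gt"] += 1
            continue
        sites.append(TrioSite(
            chrom=rec.CHROM, pos=rec.POS, ref_allele=rec.REF, alt_allele=rec.ALT[0],
            father_gt=parsed[father], mother_gt=parsed[mother], child_gt=parsed[child],
        ))
    skipped = {k: v for k, v in n_skipped.items() if v}
    if skipped:
        logger.info("%s: skipped records %s", path, skipped)
    return sites


def read_plasma_tsv(path: str | Path) -> list[PlasmaSite]:
    """Read plasma allele counts; strand and read-position columns optional.

    Read-position lists are comma-joined integers in columns
    ``read_positions_ref`` / ``read_positions_alt``.  Malformed rows raise
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PLASMA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_strand = all(c in df.columns for c in PLASMA_STRAND_COLUMNS)
    has_pos = "read_positions_ref" in df.columns and "read_positions_alt" in df.columns
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            kw: dict = {}
            if has_strand:
                kw = {c: int(getattr(row, c)) for c in PLASMA_STRAND_COLUMNS}
            if has_pos:
                for col in ("read_positions_ref", "read_positions_alt"):
                    raw = getattr(row, col)
                    if isinstance(raw, str) and raw not in ("", "."):
                        kw[col] = tuple(int(x) for x in raw.split(","))
                    else:  # empty cell: zero reads of that allele
                        kw[col] = ()
            sites.append(PlasmaSite(
                chrom=row.chrom, pos=int(row.pos),
                dep_ref=int(row.dep_ref), dep_alt=int(row.dep_alt), **kw,
            ))
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: line {i}: {err}") from None
    return sites


def write_plasma_tsv(sites: list[PlasmaSite], path: str | Path) -> None:
    cols: dict[str, list] = {
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "dep_ref": [s.dep_ref for s in sites],
        "dep_alt": [s.dep_alt for s in sites],
    }
    if sites and sites[0].has_strand:
        for c in PLASMA_STRAND_COLUMNS:
            cols[c] = [getattr(s, c) for s in sites]
    if sites and sites[0].read_positions_ref is not None:
        cols["read_positions_ref"] = [",".join(map(str, s.read_positions_ref)) for s in sites]
        cols["read_positions_alt"] = [",".join(map(str, s.read_positions_alt)) for s in sites]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_phased_panel_tsv(panel: PhasedPanel, path: str | Path) -> None:
    def col(values):
        return [v if v is not None else "." for v in values]

    pd.DataFrame({
        "chrom": [s.chrom for s in panel.sites],
        "pos": [s.pos for s in panel.sites],
        "ref": [s.ref_allele for s in panel.sites],
        "alt": [s.alt_allele for s in panel.sites],
        "P0": col(panel.paternal_hap0),
        "P1": col(panel.paternal_hap1),
        "M0": col(panel.maternal_hap0),
        "M1": col(panel.maternal_hap1),
        "info_class": [c.value for c in panel.info_class],
    }).to_csv(path, sep="\t", index=False)


def read_phased_panel_tsv(path: str | Path) -> PhasedPanel:
    """Rebuild a :class:`PhasedPanel` from its TSV serialisation.

    Trio genotypes are reconstructed from the haplotype columns (the child
    genotype is not stored; informative-site analysis does not need it, so
    the child is recorded as carrying Hap 0 of each parent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites, p0, p1, m0, m1, classes = [], [], [], [], [], []
    for row in df.itertuples(index=False):
        cls = InfoClass(row.info_class)
        haps = [None if v == "." else v for v in (row.P0, row.P1, row.M0, row.M1)]
        p0.append(haps[0]); p1.append(haps[1]); m0.append(haps[2]); m1.append(haps[3])
        classes.append(cls)
        if cls is InfoClass.UNPHASABLE:
            fgt = mgt = cgt = (row.ref, row.alt)
        else:
            fgt = (haps[0], haps[1])
            mgt = (haps[2], haps[3])
            cgt = (haps[0], haps[2])
        sites.append(TrioSite(
            chrom=row.chrom, pos=int(row.pos), ref_allele=row.ref, alt_allele=row.alt,
            father_gt=fgt, mother_gt=mgt, child_gt=cgt,
        ))
    return PhasedPanel(
        sites=sites, paternal_hap0=p0, paternal_hap1=p1,
        maternal_hap0=m0, maternal_hap1=m1, info_class=classes,
    )


def write_log_odds_tsv(result: HMMResult, path: str | Path) -> None:
    """Per-site cumulative log-odds track, plot-ready for external tools."""
    pd.DataFrame({
        "pos": result.positions,
        "state": np.asarray(result.path, dtype=int),
        "log_odds": result.log_odds,
    }).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_y_depth_tsv(path: str | Path) -> np.ndarray:
    """Per-base (or per-window) depths over the Y target region: columns
    pos, depth."""
    df = pd.read_csv(path, sep="\t")
    if "depth" not in df.columns:
        raise ValueError(f"{path}: missing 'depth' column")
    return df["depth"].to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Pipeline configuration (YAML or JSON)."""

    father: str = "father"
    mother: str = "mother"
    child: str = "child"
    gene_chrom: str = "6"
    gene_start: int = 998_300
    gene_end: int = 1_001_700
    error_rate: float = 0.005
    f_floor: float = 0.01
    min_depth: int = 40
    recomb_rate_cm_per_mb: float = 1.0
    genetic_map_path: str | None = None
    paternal_mutation: str = "pathogenic"
    maternal_mutation: str = "pathogenic"
    proband_carries_paternal: bool = True
    proband_carries_maternal: bool = True
    sex_male_min_cov4x: float = 0.50
    sex_male_min_depth: float = 20.0
    sex_female_max_cov4x: float = 0.30
    strand_bias_p: float = 1e-4
    position_bias_p: float = 1e-6
    seed: int = 0


def load_run_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def load_genetic_map(path: str | Path):
    """3-column genetic map TSV: chrom, pos, cM."""
    from nipthap.hmm import GeneticMap

    df = pd.read_csv(path, sep="\t")
    for c in ("pos", "cM"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return GeneticMap.from_table(df["pos"].to_numpy(), df["cM"].to_numpy())
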
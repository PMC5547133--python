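"""Trio phasing by Mendelian segregation and informative-SNP classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_site
from nipthap.phasing import (
    InfoClass,
    ProbandCarries,
    classify_informative,
    phase_trio,
)
from nipthap.simulator import SimConfig, simulate_family


class TestClassification:
    @pytest.mark.parametrize(
        "father,mother,expected",
        [
            ("A/G", "A/A", InfoClass.PATERNAL),
            ("A/A", "A/G", InfoClass.MATERNAL),
            ("A/A", "A/A", InfoClass.UNINFORMATIVE),
            ("A/G", "A/G", InfoClass.UNINFORMATIVE),
            ("G/G", "A/G", InfoClass.MATERNAL),  # hom-alt father still leaves one unique allele
        ],
    )
    def test_parent_heterozygosity_rule(self, father, mother, expected):
        site = make_site(100, father, mother, "A/G")
        assert classify_informative(site) == expected


class TestPhaseTrio:
    def test_paternal_het_site_forces_phase(self):
        # affected proband transmitted the paternal pathogenic haplotype
        site = make_site(100, "A/G", "A/A", "A/G")
        panel = phase_trio([site], ProbandCarries(paternal=True, maternal=True))
        assert panel.paternal_hap0 == ["G"]
        assert panel.paternal_hap1 == ["A"]
        assert panel.info_class == [InfoClass.PATERNAL]

    def test_double_het_child_het_is_unphasable(self):
        site = make_site(100, "A/G", "A/G", "A/G")
        panel = phase_trio([site])
        assert panel.info_class == [InfoClass.UNPHASABLE]
        assert panel.paternal_hap0 == [None]

    def test_double_het_child_hom_is_phased(self):
        site = make_site(100, "A/G", "A/G", "G/G")
        panel = phase_trio([site])
        assert panel.paternal_hap0 == ["G"]
        assert panel.maternal_hap0 == ["G"]
        assert panel.info_class == [InfoClass.UNINFORMATIVE]

    def test_mendelian_inconsistent_site_excluded(self):
        bad = make_site(100, "A/A", "A/A", "G/G")
        good = make_site(200, "A/G", "A/A", "A/G")
        panel = phase_trio([bad, good])
        assert panel.n_mendelian_errors == 1
        assert [s.pos for s in panel.sites] == [200]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            phase_trio([])

    def test_unsorted_positions_rejected(self):
        sites = [make_site(200, "A/G", "A/A", "A/G"), make_site(100, "A/G", "A/A", "A/G")]
        with pytest.raises(ValueError, match="sorted"):
            phase_trio(sites)

    def test_informative_partition_counts(self):
        """A panel built with 830 paternal- and 534 maternal-informative sites
        is classified back into exactly those counts."""
        sites = []
        pos = 0
        for _ in range(830):
            pos += 10
            sites.append(make_site(pos, "A/G", "A/A", "A/G"))
        for _ in range(534):
            pos += 10
            sites.append(make_site(pos, "A/A", "A/G", "A/G"))
        panel = phase_trio(sites)
        counts = panel.class_counts()
        assert counts[InfoClass.PATERNAL] == 830
        assert counts[InfoClass.MATERNAL] == 534
        assert len(panel.sites) == 1364


@st.composite
def trio_genotypes(draw):
    """Random Mendelian-consistent trio at a biallelic site."""
    f = (draw(st.sampled_from("AG")), draw(st.sampled_from("AG")))
    m = (draw(st.sampled_from("AG")), draw(st.sampled_from("AG")))
    c = (f[draw(st.integers(0, 1))], m[draw(st.integers(0, 1))])
    return f, m, c


class TestProperties:
    @given(st.lists(trio_genotypes(), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=100)
    def test_transmitted_alleles_reconstruct_child(self, gts):
        sites = [
            make_site(10 * (i + 1), "/".join(f), "/".join(m), "/".join(c))
            for i, (f, m, c) in enumerate(gts)
        ]
        panel = phase_trio(sites)
        for i, site in enumerate(panel.sites):
            if panel.info_class[i] is InfoClass.UNPHASABLE:
                continue
            # proband carries Hap 0 of each parent by default
            rebuilt = tuple(sorted((panel.paternal_hap0[i], panel.maternal_hap0[i])))
            assert rebuilt == tuple(sorted(site.child_gt))

    @given(st.lists(trio_genotypes(), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_swapping_linkage_annotation_swaps_hap_labels_only(self, gts):
        sites = [
            make_site(10 * (i + 1), "/".join(f), "/".join(m), "/".join(c))
            for i, (f, m, c) in enumerate(gts)
        ]
        a = phase_trio(sites, ProbandCarries(paternal=True, maternal=True))
        b = phase_trio(sites, ProbandCarries(paternal=False, maternal=False))
        assert a.paternal_hap0 == b.paternal_hap1
        assert a.paternal_hap1 == b.paternal_hap0
        assert a.maternal_hap0 == b.maternal_hap1
        assert a.info_class == b.info_class


class TestSimulatorRecovery:
    def test_phasing_recovers_true_parental_haplotypes(self):
        family = simulate_family(SimConfig(n_snps=400, seed=7))
        panel = phase_trio(family.trio_sites())
        assert panel.n_mendelian_errors == 0
        pos_to_idx = {int(p): i for i, p in enumerate(family.positions)}
        checked = 0
        for i, site in enumerate(panel.sites):
            if panel.info_class[i] in (InfoClass.UNPHASABLE, InfoClass.UNINFORMATIVE):
                continue
            j = pos_to_idx[site.pos]
            letters = np.array([site.ref_allele, site.alt_allele])
            assert panel.paternal_hap0[i] == letters[family.father_haps[0, j]]
            assert panel.paternal_hap1[i] == letters[family.father_haps[1, j]]
            assert panel.maternal_hap0[i] == letters[family.mother_haps[0, j]]
            assert panel.maternal_hap1[i] == letters[family.mother_haps[1, j]]
            checked += 1
        assert checked > 200
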
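"""HAF screening, amplicon/primer design, assignment, and the pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import diagnostic_oracle, make_vt, random_popmap, random_vt
from snptrace import simdata
from snptrace.io_formats import PopulationMap
from snptrace.markerfinder import (AmpliconCandidate, DiagnosticSite,
                                   HafThresholds, PipelineConfig,
                                   PrimerConstraints, assign_population,
                                   compute_haf, design_primer_pairs,
                                   extract_amplicon, find_diagnostic_sites,
                                   annotate_sites_with_genes, gc_percent,
                                   run_traceability_pipeline, validate_primer)


def _two_pop_vt(pop_a, pop_b):
    """One site; genotype strings per population."""
    vt = make_vt([pop_a + pop_b])
    pm = PopulationMap({f"s{i + 1}": ("A" if i < len(pop_a) else "B")
                       for i in range(len(pop_a) + len(pop_b))})
    return vt, pm


class TestHaf:
    def test_direct_count(self):
        vt, pm = _two_pop_vt(["1/1"] * 4 + ["0/1"], ["0/0"] * 3)
        assert compute_haf(vt, pm, "A", 0, "C") == pytest.approx(0.8)

    def test_all_hom_ref(self):
        vt, pm = _two_pop_vt(["0/0"] * 5, ["0/0"] * 3)
        assert compute_haf(vt, pm, "A", 0, "A") == 1.0

    def test_missing_excluded_from_denominator(self):
        vt, pm = _two_pop_vt(["1/1", "1/1", "./."], ["0/0"])
        assert compute_haf(vt, pm, "A", 0, "C") == 1.0

    def test_unknown_allele_rejected(self):
        vt, pm = _two_pop_vt(["0/0"], ["1/1"])
        with pytest.raises(ValueError):
            compute_haf(vt, pm, "A", 0, "T")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_partition_property(self, seed):
        """HAF(ref) + HAF(alt) <= 1, equality iff no heterozygote called."""
        rng = np.random.default_rng(seed)
        vt = random_vt(rng, n_samples=7, n_sites=5, missing_rate=0.2)
        pm = PopulationMap({s: "A" for s in vt.samples})
        for i in range(vt.n_sites):
            r = compute_haf(vt, pm, "A", i, "A")
            a = compute_haf(vt, pm, "A", i, "G")
            if np.isnan(r):
                continue
            called = vt.genotypes[i][np.all(vt.genotypes[i] >= 0, axis=1)]
            has_het = bool(np.any(called[:, 0] != called[:, 1]))
            assert r + a <= 1 + 1e-12
            assert (r + a == pytest.approx(1.0)) != has_het


class TestFindDiagnosticSites:
    def test_fixed_difference_reported_both_ways(self):
        vt, pm = _two_pop_vt(["1/1"] * 3, ["0/0"] * 3)
        sites = find_diagnostic_sites(vt, pm, 1.0)
        assert {(s.focal_pop, s.focal_allele) for s in sites} == {
            ("A", "C"), ("B", "A")}

    def test_threshold_sensitivity(self):
        vt, pm = _two_pop_vt(["1/1"] * 4 + ["0/1"], ["0/0"] * 4)
        found_08 = find_diagnostic_sites(vt, pm, 0.8)
        assert ("A", "C") in {(s.focal_pop, s.focal_allele) for s in found_08}
        found_09 = find_diagnostic_sites(vt, pm, 0.9)
        assert all(s.focal_pop != "A" for s in found_09)

    def test_polymorphic_counter_population_blocks(self):
        vt, pm = _two_pop_vt(["1/1"] * 3, ["0/0", "0/0", "0/1"])
        assert all(s.focal_pop != "A"
                   for s in find_diagnostic_sites(vt, pm, 1.0))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n_samples = int(rng.integers(4, 21))
            n_sites = int(rng.integers(5, 120))
            vt = random_vt(rng, n_samples, n_sites, missing_rate=0.15)
            pm = random_popmap(rng, vt.samples, int(rng.integers(2, 5)))
            t = float(rng.choice([0.8, 0.9, 1.0]))
            got = {(s.contig, s.pos, s.focal_pop,
                    0 if s.focal_allele == "A" else 1)
                   for s in find_diagnostic_sites(vt, pm, t)}
            assert got == diagnostic_oracle(vt, pm, t)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(15)
        vt = random_vt(rng, 12, 150, missing_rate=0.1)
        pm = random_popmap(rng, vt.samples, 3)
        keys = [{(s.pos, s.focal_pop, s.focal_allele)
                 for s in find_diagnostic_sites(vt, pm, t)}
                for t in (0.8, 0.9, 1.0)]
        assert keys[2] <= keys[1] <= keys[0]


class TestGeneAnnotation:
    def _sites(self, positions):
        return [DiagnosticSite("chr1", p, "A", "C", "A", 1.0, 1.0)
                for p in positions]

    def test_target_gating(self, default_scenario):
        genes = default_scenario.genes
        target = genes[0]
        inside = target.longest_transcript[1][0][0] + 1
        outside_gene = genes[-1]
        in_other = outside_gene.longest_transcript[1][0][0] + 1
        out = annotate_sites_with_genes(self._sites([inside, in_other]),
                                        genes, {target.gene_id})
        assert [(s.pos, s.gene_id) for s in out] == [(inside, target.gene_id)]

    def test_no_annotation_mode_passes_through(self):
        sites = self._sites([5, 10, 15])
        out = annotate_sites_with_genes(sites, None, None)
        assert len(out) == 3 and all(s.gene_id == "" for s in out)


class TestAmplicon:
    REF = {"c": "ACGTA" * 100}  # 500 bp

    def _site(self, pos):
        return DiagnosticSite("c", pos, "A", "C", "A", 1.0, 1.0)

    def test_small_flank_window(self):
        amp = extract_amplicon(self.REF, self._site(100), flank=10)
        assert len(amp.sequence) == 21
        assert amp.site_offset == 10
        assert amp.sequence[10] == self.REF["c"][99]

    def test_near_edge_skipped(self):
        assert extract_amplicon(self.REF, self._site(100), flank=900) is None
        assert extract_amplicon(self.REF, self._site(5), flank=10) is None

    def test_default_flank_window_length(self, default_scenario):
        scn = default_scenario
        c, p, pop, a = scn.truth[0]
        site = DiagnosticSite(c, p, pop, a, "N", 1.0, 1.0)
        amp = extract_amplicon(scn.reference, site, flank=900)
        assert len(amp.sequence) == 1801
        assert amp.sequence[900] == scn.reference[c][p - 1]


class TestPrimerDesign:
    def test_published_style_primer_passes_validators(self):
        seq = "TATCAGAGGAGGGATCAAATGA"
        assert len(seq) == 22
        assert gc_percent(seq) == pytest.approx(100 * 9 / 22)
        assert validate_primer(seq)

    def test_designed_pairs_satisfy_all_constraints(self, default_scenario):
        scn = default_scenario
        pc = PrimerConstraints()
        c, p, pop, a = scn.truth[1]
        amp = extract_amplicon(scn.reference,
                               DiagnosticSite(c, p, pop, a, "N", 1.0, 1.0))
        pairs = design_primer_pairs(amp, pc, max_pairs=5)
        assert pairs
        for pr in pairs:
            for seq, tm, gc in [(pr.left_seq, pr.tm_left, pr.gc_left),
                                (pr.right_seq, pr.tm_right, pr.gc_right)]:
                assert pc.size[0] <= len(seq) <= pc.size[2]
                assert pc.tm[0] <= tm <= pc.tm[2]
                assert pc.gc[0] <= gc <= pc.gc[2]
            assert abs(pr.tm_left - pr.tm_right) <= pc.max_tm_diff
            assert pc.product_size[0] <= pr.product_len <= pc.product_size[1]
            # product spans the diagnostic site
            assert pr.left_start + len(pr.left_seq) <= amp.site_offset
            assert pr.left_start + pr.product_len > amp.site_offset
            # right primer is the reverse strand of the product's 3' end
            rc = amp.sequence[pr.right_start:pr.right_start + len(pr.right_seq)]
            comp = rc.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert comp == pr.right_seq

    def test_homopolymer_amplicon_infeasible(self):
        amp = AmpliconCandidate(
            DiagnosticSite("c", 500, "A", "C", "A", 1.0, 1.0),
            "A" * 1801, 900)
        assert design_primer_pairs(amp) == []


class TestAssignment:
    PANEL = [
        DiagnosticSite("c", 10, "P1", "C", "A", 1.0, 1.0),
        DiagnosticSite("c", 20, "P1", "G", "T", 1.0, 1.0),
        DiagnosticSite("c", 30, "P2", "T", "C", 1.0, 1.0),
        DiagnosticSite("c", 40, "P2", "A", "G", 1.0, 1.0),
    ]

    def test_perfect_match(self):
        geno = {("c", 10): "CC", ("c", 20): "GG",
                ("c", 30): "CC", ("c", 40): "GG"}
        res = assign_population(self.PANEL, geno)
        assert res.call == "P1" and res.score == 1.0

    def test_all_heterozygous_unassigned(self):
        geno = {("c", 10): "AC", ("c", 20): "GT",
                ("c", 30): "CT", ("c", 40): "AG"}
        assert assign_population(self.PANEL, geno).call == "unassigned"

    def test_tie_unassigned(self):
        geno = {("c", 10): "CC", ("c", 30): "TT"}
        assert assign_population(self.PANEL, geno).call == "unassigned"

    def test_zero_typed_markers_rejected(self):
        with pytest.raises(ValueError):
            assign_population(self.PANEL, {})


class TestPipeline:
    def test_planted_recovery_and_primers(self, default_scenario,
                                          scenario_paths):
        cfg = PipelineConfig(vcf=str(scenario_paths["vcf"]),
                             popmap=str(scenario_paths["popmap"]),
                             reference=str(scenario_paths["reference"]),
                             gff=str(scenario_paths["gff"]))
        res = run_traceability_pipeline(cfg)
        truth = {(c, p, pop) for c, p, pop, a in default_scenario.truth}
        found = {(s.contig, s.pos, s.focal_pop) for s in res.diagnostic_sites}
        assert found == truth
        pops_with_primers = {s.focal_pop for s, _, _ in res.markers}
        assert pops_with_primers == set(
            default_scenario.population_map.populations)

    def test_no_annotation_mode(self, scenario_paths):
        cfg = PipelineConfig(vcf=str(scenario_paths["vcf"]),
                             popmap=str(scenario_paths["popmap"]),
                             reference=str(scenario_paths["reference"]),
                             gff=None)
        res = run_traceability_pipeline(cfg)
        assert res.markers and all(s.gene_id == ""
                                   for s, _, _ in res.markers)

    def test_deterministic_rerun(self, scenario_paths):
        cfg = PipelineConfig(vcf=str(scenario_paths["vcf"]),
                             popmap=str(scenario_paths["popmap"]),
                             reference=str(scenario_paths["reference"]),
                             gff=str(scenario_paths["gff"]))
        a = run_traceability_pipeline(cfg).marker_table().to_csv()
        b = run_traceability_pipeline(cfg).marker_table().to_csv()
        assert a == b
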
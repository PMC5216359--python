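import numpy as np
import pytest

from barcodeauth.assay import (BGL_I, ITS2F, Amplicon, Enzyme, PcrConstraints,
                               Primer, differential_digestion, digest,
                               engineer_primer, find_motif_sites,
                               find_primer_sites, in_silico_pcr, select_assay)
from barcodeauth.seqio import IUPAC_SETS, reverse_complement

from conftest import make_table


def naive_motif_scan(seq, motif):
    """O(n*m) oracle for plus-strand degenerate matching."""
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(seq[i + k] in "ACGT" and seq[i + k] in IUPAC_SETS[motif[k]]
               for k in range(len(motif))):
            hits.append(i + 1)
    return hits


class TestMotifScan:
    def test_no_site(self):
        assert find_motif_sites("AAAAAA", BGL_I) == []

    def test_minimal_site(self):
        assert find_motif_sites("GCCAAAAAGGC", BGL_I) == [(1, "+")]

    def test_matches_naive_scan_on_random_sequences(self):
        rng = np.random.default_rng(123)
        enzymes = [BGL_I, Enzyme("EcoRI", "GAATTC", 1), Enzyme("toy", "GNC", 1)]
        for _ in range(10_000):
            enz = enzymes[rng.integers(0, len(enzymes))]
            seq = "".join(rng.choice(list("ACGTN"), rng.integers(5, 40)))
            plus = [p for p, s in find_motif_sites(seq, enz, both_strands=False)]
            assert plus == naive_motif_scan(seq, enz.motif)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), 50))
            fwd = {p for p, _ in find_motif_sites(seq, BGL_I)}
            mirrored = {len(seq) - (p + len(BGL_I.motif) - 1) + 1
                        for p, _ in find_motif_sites(reverse_complement(seq), BGL_I)}
            assert fwd == mirrored

    def test_ambiguous_template_base_never_matches(self):
        assert find_motif_sites("GCCAAAAAGGN", BGL_I) == []

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError):
            find_motif_sites("GCC-AAAAGGC", BGL_I)


class TestDigest:
    def test_no_site_single_fragment(self):
        amp = Amplicon("t", 1, 20, "A" * 20)
        assert digest(amp, BGL_I).fragments == (20,)

    def test_paper_sized_fragments(self):
        # 292-base product with one site whose top-strand cut falls after base
        # 168 (site start 162, cut offset 7): manual coordinate arithmetic
        product = list("AT" * 146)
        product[161:172] = list("GCCTTTTTGGC")
        amp = Amplicon("t", 1, 292, "".join(product))
        pat = digest(amp, BGL_I)
        assert pat.fragments == (168, 124)
        assert pat.cuts == (168,)

    def test_two_sites_three_fragments(self):
        product = ["A"] * 100
        product[9:20] = list("GCCTTTTTGGC")
        product[59:70] = list("GCCTTTTTGGC")
        amp = Amplicon("t", 1, 100, "".join(product))
        pat = digest(amp, BGL_I)
        assert len(pat.fragments) == 3
        assert sum(pat.fragments) == 100

    def test_fragment_sum_conservation_random(self):
        rng = np.random.default_rng(77)
        for _ in range(500):
            L = int(rng.integers(20, 400))
            seq = "".join(rng.choice(list("ACGT"), L))
            pat = digest(Amplicon("t", 1, L, seq), BGL_I)
            assert sum(pat.fragments) == L
            assert all(f >= 1 for f in pat.fragments)
            assert len(pat.fragments) == len(pat.cuts) + 1


class TestPrimerSites:
    def test_verbatim_forward_binding(self):
        template = "TTTT" + ITS2F.sequence + "GGGG"
        (b,) = find_primer_sites(template, ITS2F)
        assert (b.start, b.end, b.mismatches) == (5, 24, 0)

    def test_reverse_binding_coordinates(self):
        rev = Primer("r", "ACGTACGTACGT", "reverse")
        template = "TT" + reverse_complement(rev.sequence) + "AA"
        (b,) = find_primer_sites(template, rev)
        assert (b.start, b.end, b.strand) == (3, 14, "-")

    def test_internal_mismatch_tolerated(self):
        # mismatch at the 13th primer base (5'-counted): within budget, clamp ok
        rev = Primer("r", "ACGTACGTACGTGCCTACG", "reverse")
        footprint = reverse_complement(rev.sequence)
        mism = list(footprint)
        # primer base 13 corresponds to footprint position len - 13 = 6 (0-based)
        mism[len(mism) - 13] = "A" if mism[len(mism) - 13] != "A" else "C"
        template = "TT" + "".join(mism) + "AA"
        (b,) = find_primer_sites(template, rev)
        assert b.mismatches == 1

    def test_three_prime_clamp_mismatch_rejected(self):
        fwd = Primer("f", "ACGTACGTACGTACG", "forward")
        broken = fwd.sequence[:-1] + ("A" if fwd.sequence[-1] != "A" else "C")
        template = "TT" + broken + "AA"
        assert find_primer_sites(template, fwd) == []

    def test_primer_longer_than_template(self):
        assert find_primer_sites("ACGT", ITS2F) == []


class TestInSilicoPcr:
    def build_template(self, insert_len=100, rev=None):
        rng = np.random.default_rng(5)
        rev = rev or Primer("r", "TGGGTCATCTTCTCCCAGC", "reverse")
        core = "".join(rng.choice(list("ACGT"), insert_len))
        return ("TTTTT" + ITS2F.sequence + core + reverse_complement(rev.sequence)
                + "AAAAA"), rev

    def test_missing_reverse_site_no_product(self):
        template = "TTTT" + ITS2F.sequence + "G" * 100
        rev = Primer("r", "TGGGTCATCTTCTCCCAGC", "reverse")
        assert in_silico_pcr(template, ITS2F, rev) == []

    def test_planted_292bp_product(self):
        rev = Primer("r", "TGGGTCATCTTCTCCCAGC", "reverse")
        template, rev = self.build_template(292 - len(ITS2F.sequence) - len(rev.sequence), rev)
        (amp,) = in_silico_pcr(template, ITS2F, rev)
        assert amp.length == 292
        assert amp.product.startswith(ITS2F.sequence)
        assert amp.product.endswith(reverse_complement(rev.sequence))

    def test_primer_overwrite_removes_site_under_engineered_primer(self):
        # template carries a Bgl I site overlapping the reverse footprint; an
        # engineered primer (1 internal substitution) erases it from the product
        rng = np.random.default_rng(8)
        core = "".join(rng.choice(list("ACGT"), 80))
        footprint = "ACTAGCCTATTTGGCTCAT"  # contains GCCTATTTGGC (a Bgl I site)
        assert naive_motif_scan(footprint, BGL_I.motif)
        template = "TT" + ITS2F.sequence + core + footprint + "AA"
        exact = Primer("exact", reverse_complement(footprint), "reverse")
        (amp0,) = in_silico_pcr(template, ITS2F, exact)
        assert find_motif_sites(amp0.product, BGL_I)  # site present with exact primer
        eng_seq = list(exact.sequence)
        k = exact.sequence.index("GGC")  # complement of the GCC triplet, 5' half
        eng_seq[k] = "T"
        eng = Primer("eng", "".join(eng_seq), "reverse")
        (amp1,) = in_silico_pcr(template, ITS2F, eng)
        assert find_motif_sites(amp1.product, BGL_I) == []

    def test_length_bounds_respected(self):
        template, rev = self.build_template(100)
        assert in_silico_pcr(template, ITS2F, rev,
                             PcrConstraints(min_len=300, max_len=400)) == []


def planted_library():
    """Three species mirroring the assay logic: target amplifies and cuts,
    congener amplifies but lacks the site, adulterant does not amplify."""
    rng = np.random.default_rng(21)
    core = list(rng.choice(list("ACGT"), 120))
    core[40:51] = list("GCCAATTTGGA")  # near-site: target completes it
    footprint = "ACTATGACTATTTACTCAT"
    tgt_core = core.copy()
    tgt_core[50] = "C"  # GCCAATTTGGC: target-only Bgl I site
    def build(c, fp):
        return "TT" + ITS2F.sequence + "".join(c) + fp + "AA"
    rev = Primer("rev", reverse_complement(footprint), "reverse")
    templates = {
        "t1": build(tgt_core, footprint),
        "c1": build(core, footprint),
        "a1": build(core, "G" * len(footprint)),
    }
    table = make_table({"t1": ("tgt", "target"), "c1": ("near", "congener"),
                        "a1": ("far", "adulterant")})
    return templates, table, rev


class TestDifferentialDigestion:
    def test_planted_three_way_contract(self):
        templates, table, rev = planted_library()
        design = differential_digestion(templates, table, ITS2F, rev, BGL_I,
                                        target="tgt")
        assert design.per_species["tgt"].amplifies and design.per_species["tgt"].cut
        assert design.per_species["near"].amplifies and not design.per_species["near"].cut
        assert not design.per_species["far"].amplifies
        assert design.discriminates

    def test_enzyme_without_sites_no_discrimination(self):
        templates, table, rev = planted_library()
        absent = Enzyme("never", "GCGCGCGCGCGC", 6)
        design = differential_digestion(templates, table, ITS2F, rev, absent,
                                        target="tgt")
        assert not design.discriminates

    def test_single_species_rejected(self):
        templates, table, rev = planted_library()
        only = {"t1": templates["t1"]}
        with pytest.raises(ValueError):
            differential_digestion(only, table, ITS2F, rev, BGL_I, target="tgt")


class TestEngineerPrimer:
    def test_site_free_footprint_returns_original(self):
        templates, table, rev = planted_library()
        # footprint region carries no site in any template
        ref = templates["c1"]
        start = ref.index("ACTATGACTATTTACTCAT") + 1
        fp = (start, start + 18)
        proposals, tally = engineer_primer({"near": templates["c1"], "tgt": templates["t1"]},
                                           fp, BGL_I, reference=ref)
        assert proposals and proposals[0].sequence == reverse_complement(
            "ACTATGACTATTTACTCAT")

    def test_single_substitution_destroys_confounding_site(self, default_library):
        records, table, truth = default_library
        species_templates = {}
        for sp, grp in truth.species_groups.items():
            if grp in ("target", "congener"):
                sid = next(s for s, x in truth.samples.items() if x == sp)
                species_templates[sp] = next(r.residues for r in records if r.id == sid)
        ref = species_templates[truth.target_species]
        proposals, tally = engineer_primer(species_templates,
                                           truth.rev_footprint_template, BGL_I,
                                           reference=ref)
        assert proposals
        # the planted single-substitution repair (13th-base G->T) is proposed
        assert truth.rev_primer_engineered in {p.sequence for p in proposals}
        # closed loop: re-check every proposal through PCR + digestion
        for prop in proposals:
            for sp, template in species_templates.items():
                amps = in_silico_pcr(template, ITS2F, prop)
                assert amps, f"{prop.sequence} fails to amplify {sp}"
                for amp in amps:
                    lo = amp.length - len(prop.sequence) + 1
                    overl = [h for h in find_motif_sites(amp.product, BGL_I)
                             if h[0] + len(BGL_I.motif) - 1 >= lo]
                    assert overl == []

    def test_clamp_only_repair_yields_empty_with_tally(self):
        # a reverse primer's 3'-clamp covers the first plus-strand bases of its
        # footprint; plant a site whose only in-footprint defined bases (GGC)
        # sit exactly there, with its GCC half upstream in the amplicon core,
        # so no allowed substitution can destroy it
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), 52)) + "GCCTATTT"
        footprint = "GGCTGACTATTTACTACTA"
        template = "TT" + ITS2F.sequence + core + footprint + "AA"
        assert naive_motif_scan(core[-8:] + footprint[:3], BGL_I.motif)
        start = template.index(footprint) + 1
        fp = (start, start + len(footprint) - 1)
        proposals, tally = engineer_primer({"sp": template}, fp, BGL_I,
                                           reference=template)
        assert proposals == []
        assert tally["clamp"] > 0
        assert tally["footprint_site_remains"] > 0


class TestSelectAssay:
    def test_clean_design_ranked_first(self):
        templates, table, rev = planted_library()
        ref = templates["t1"]
        start = ref.index("ACTATGACTATTTACTCAT") + 1
        designs = select_assay(templates, table, "tgt", [BGL_I],
                               [(start, start + 18)])
        assert designs and designs[0].discriminates
        assert not designs[0].engineered

    def test_engineered_design_found_for_synthetic_mirror(self, default_library):
        records, table, truth = default_library
        templates = {r.id: r.residues for r in records}
        designs = select_assay(templates, table, truth.target_species, [BGL_I],
                               [truth.rev_footprint_template])
        assert designs
        best = designs[0]
        assert best.discriminates and best.engineered and best.n_substitutions == 1
        tgt = best.per_species[truth.target_species]
        assert tgt.pattern.fragments == truth.expected_fragments

    def test_absent_motif_yields_empty(self):
        templates, table, rev = planted_library()
        ref = templates["t1"]
        start = ref.index("ACTATGACTATTTACTCAT") + 1
        absent = Enzyme("never", "GCGCGCGCGCGC", 6)
        assert select_assay(templates, table, "tgt", [absent],
                            [(start, start + 18)]) == []
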
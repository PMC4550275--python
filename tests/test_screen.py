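"""Structural filters and candidate classification."""

import json

import numpy as np
import pytest

from lcpufa.screen import (
    MOTIF_FILTERS,
    CandidateCall,
    ScreenConfig,
    check_elovl_structure,
    check_fad_structure,
    classify_candidate,
    classify_residue,
    screen_transcriptome,
)
from lcpufa.seqio import SeqRecord
from lcpufa.synth import (
    ELOVL_BOX_POS,
    FAD_HPGG_POS,
    SynthParams,
    _member_protein,
    elovl_reference,
    make_elovl_gene,
    make_fad_gene,
    make_transcriptome,
)


def _ev(results):
    return {name: ok for name, ok, _ in results}


@pytest.fixture
def fad_protein(rng):
    protein, _, _ = _member_protein("Fad", 432, rng, 0.05)
    return protein


@pytest.fixture
def elovl_protein(rng):
    protein, _, _ = _member_protein("Elovl", 294, rng, 0.05)
    return protein


class TestFadStructure:
    def test_clean_scaffold_passes_all(self, fad_protein, cfg):
        assert all(ok for _, ok, _ in check_fad_structure(fad_protein, cfg))

    def test_hpgg_deletion_flips_only_its_filter(self, fad_protein, cfg):
        lesioned = fad_protein.replace("HPGG", "EKRD")
        ev = _ev(check_fad_structure(lesioned, cfg))
        baseline = _ev(check_fad_structure(fad_protein, cfg))
        assert not ev["haeme_hpgg_nterm"]
        for name in set(ev) - {"haeme_hpgg_nterm"}:
            assert ev[name] == baseline[name]

    @pytest.mark.parametrize(
        "box,filter_name",
        [("fad_box2", "fad_box2"), ("fad_box3", "fad_box3")],
    )
    def test_single_box_lesion_bijection(self, fad_protein, cfg, box, filter_name):
        """Knocking out one histidine box flips exactly its own filter."""
        from lcpufa.motif import scan
        from lcpufa.profiles import load_builtin_profiles

        prof = load_builtin_profiles()
        hits = scan(fad_protein, prof.patterns[box])
        assert hits
        start = hits[0].start
        lesioned = (
            fad_protein[:start] + "EKRDN"[: prof.patterns[box].length]
            + fad_protein[start + prof.patterns[box].length :]
        )
        ev = _ev(check_fad_structure(lesioned, cfg))
        baseline = _ev(check_fad_structure(fad_protein, cfg))
        assert not ev[filter_name]
        for name in set(ev) - {filter_name}:
            assert ev[name] == baseline[name]

    def test_box1_lesion_caught_by_order_filter(self, fad_protein, cfg):
        """The first box's pattern (HXXXH) is also satisfied by any HXXHH
        window, so its knockout surfaces as an ordering failure: no HXXXH
        hit remains upstream of the second box."""
        from lcpufa.motif import scan
        from lcpufa.profiles import load_builtin_profiles

        prof = load_builtin_profiles()
        start = scan(fad_protein, prof.patterns["fad_box1"])[0].start
        lesioned = fad_protein[:start] + "EKRDN" + fad_protein[start + 5 :]
        ev = _ev(check_fad_structure(lesioned, cfg))
        assert not ev["box_order"]
        assert not all(ev.values())

    def test_scrambled_box_order_fails(self, cfg):
        """QXXHH ... HXXXH layout admits no increasing chain."""
        linker = "EKRDNQSG" * 40
        protein = (
            "M" + linker[:28] + "HPGG" + linker[:40] + "QIEHH"
            + linker[:60] + "HYQHH" + linker[:60] + "HDFGH" + linker[:60]
        )
        ev = _ev(check_fad_structure(protein, cfg))
        assert ev["fad_box1"] and ev["fad_box2"] and ev["fad_box3"]
        assert not ev["box_order"]

    def test_hpgg_beyond_nterm_limit_fails(self, cfg):
        linker = "EKRDNQSG" * 50
        protein = "M" + linker[:120] + "HPGG" + linker[:100]
        ev = _ev(check_fad_structure(protein, cfg))
        assert not ev["haeme_hpgg_nterm"]


class TestElovlStructure:
    def test_clean_scaffold_17_matches(self, elovl_protein, cfg, refs):
        results = check_elovl_structure(
            elovl_protein, refs.elovl_reference, cfg
        )
        ev = _ev(results)
        assert all(ev.values())
        detail = next(d for n, _, d in results if n == "residue_checklist")
        assert detail.startswith("17 match")

    def test_conservative_substitution_still_passes(self, elovl_protein, cfg, refs):
        # T -> S at checklist position 132 (1-based), a conservative pair
        pos = 131  # 0-based
        assert elovl_protein[pos] == "T"
        mutated = elovl_protein[:pos] + "S" + elovl_protein[pos + 1 :]
        results = check_elovl_structure(mutated, refs.elovl_reference, cfg)
        ev = _ev(results)
        assert ev["residue_checklist"]
        detail = next(d for n, _, d in results if n == "residue_checklist")
        assert "1 conservative" in detail

    def test_three_nonconservative_mismatches_fail(self, elovl_protein, cfg, refs):
        mutated = list(elovl_protein)
        for pos0 in (124, 127, 177):  # K125, E128, N178 -> W (non-conservative)
            mutated[pos0] = "W"
        results = check_elovl_structure(
            "".join(mutated), refs.elovl_reference, cfg
        )
        assert not _ev(results)["residue_checklist"]

    def test_box_knockout(self, elovl_protein, cfg, refs):
        lesioned = (
            elovl_protein[:ELOVL_BOX_POS] + "EKRDN"
            + elovl_protein[ELOVL_BOX_POS + 5 :]
        )
        assert not _ev(
            check_elovl_structure(lesioned, refs.elovl_reference, cfg)
        )["elovl_box"]


@pytest.mark.parametrize("res,expected,kind", [
    ("T", "T", "match"),
    ("S", "T", "conservative"),
    ("V", "L", "conservative"),
    ("A", "L", "conservative"),
    ("W", "T", "mismatch"),
    (None, "T", "mismatch"),
])
def test_classify_residue(res, expected, kind):
    assert classify_residue(res, expected) == kind


class TestClassify:
    def test_short_contig_rejected(self, cfg, refs):
        rec = SeqRecord(id="short", residues="ACGT" * 45, alphabet="nucleotide")
        call = classify_candidate(rec, cfg, refs)
        assert call.status == "rejected"
        assert "200" in call.detail

    def test_planted_genes_recovered(self, cfg, refs):
        rng = np.random.default_rng(11)
        params = SynthParams(seed=11)
        fad = make_fad_gene(rng, params, record_id="f")
        call = classify_candidate(fad.record, cfg, refs)
        assert (call.family, call.status) == ("Fad", "functional")
        elovl = make_elovl_gene(rng, params, record_id="e")
        call = classify_candidate(elovl.record, cfg, refs)
        assert (call.family, call.status) == ("Elovl", "functional")

    def test_random_decoys_yield_no_functional(self, cfg, refs):
        rng = np.random.default_rng(7)
        for i in range(100):
            length = int(rng.integers(300, 1600))
            rec = SeqRecord(
                id=f"d{i}",
                residues="".join("ACGT"[b] for b in rng.integers(0, 4, length)),
                alphabet="nucleotide",
            )
            assert classify_candidate(rec, cfg, refs).status != "functional"

    def test_deterministic(self, cfg, refs):
        rng = np.random.default_rng(3)
        gene = make_fad_gene(rng, SynthParams(seed=3), record_id="g")
        c1 = classify_candidate(gene.record, cfg, refs)
        c2 = classify_candidate(gene.record, cfg, refs)
        assert (c1.family, c1.status, c1.evidence) == (
            c2.family, c2.status, c2.evidence
        )


class TestScreenTranscriptome:
    def test_counts_and_reports(self, tmp_path, cfg, refs):
        params = SynthParams(seed=42, n_decoys=10)
        records, truth, genes = make_transcriptome(params, out_dir=tmp_path / "sim")
        table = screen_transcriptome(
            tmp_path / "sim" / "contigs.fasta", cfg, refs, out_dir=tmp_path / "out"
        )
        assert len(table) == 26  # 16 planted + 10 decoys
        merged = table.merge(
            truth[["record_id", "expected_status"]], on="record_id", how="inner"
        )
        assert (merged["status"] == merged["expected_status"]).all()
        assert (tmp_path / "out" / "calls.tsv").exists()
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["n_records"] == 26

    def test_byte_identical_reports(self, tmp_path, cfg, refs):
        params = SynthParams(seed=5, n_decoys=5)
        make_transcriptome(params, out_dir=tmp_path / "sim")
        for d in ("o1", "o2"):
            screen_transcriptome(
                tmp_path / "sim" / "contigs.fasta", cfg, refs,
                out_dir=tmp_path / d,
            )
        assert (tmp_path / "o1" / "calls.tsv").read_bytes() == (
            tmp_path / "o2" / "calls.tsv"
        ).read_bytes()

    def test_one_call_per_record(self, tmp_path, cfg, refs):
        params = SynthParams(seed=6, n_decoys=5)
        records, _, _ = make_transcriptome(params, out_dir=tmp_path / "sim")
        table = screen_transcriptome(
            tmp_path / "sim" / "contigs.fasta", cfg, refs
        )
        assert table["record_id"].is_unique
        assert len(table) == len(records)
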
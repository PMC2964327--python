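"""Tag resolution, failure classification, tag-set validation and primer
coverage scanning."""

from __future__ import annotations

import random

import pytest

from v6prof._seq import revcomp
from v6prof.demux import (
    FailureClass,
    PrimerPair,
    demux_read,
    demux_run,
    primer_coverage,
    validate_tag_set,
)
from v6prof.formats import SampleSheet, SequenceRecord, TagEntry, TagTable
from v6prof.merge import CompositeRead
from v6prof.simulate import SimConfig, simulate_run


def _rand_v6(seed: int, n: int = 76) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _composite(seq: str) -> CompositeRead:
    return CompositeRead(
        id="c", seq=seq, qual=[40] * len(seq), overlap_len=30,
        overlap_mismatches=0, status="perfect",
    )


@pytest.fixture(scope="module")
def sheet0(tags) -> SampleSheet:
    sheet = SampleSheet([
        ("0-v6L", "0-v6R", "s0"),
        ("14-v6L", "0-v6R", "s14"),
        ("9-v6L", "0-v6R", "s9"),
    ])
    sheet.validate_against(tags)
    return sheet


def _amplicon(ltag: str, rtag: str, primers: PrimerPair, v6: str, r_base="G") -> str:
    left = primers.left.replace("R", r_base)
    return ltag + left + v6 + revcomp(primers.right) + revcomp(rtag)


def test_published_tag_pair_resolves(tags, primers, sheet0):
    v6 = _rand_v6(1)
    comp = _composite(_amplicon("CATGCG", "CGCATG", primers, v6))
    rec = demux_read(comp, tags, primers, sheet0)
    assert not isinstance(rec, FailureClass)
    assert rec.left_tag_name == "0-v6L"
    assert rec.right_tag_name == "0-v6R"
    assert rec.sample_id == "s0"
    assert rec.interprimer_seq == v6
    assert rec.left_primer_mm == 0 and rec.right_primer_mm == 0
    assert not rec.n1_ambiguous


def test_missing_left_tag_is_tag_absent(tags, primers, sheet0):
    comp = _composite(_amplicon("", "CGCATG", primers, _rand_v6(2)))
    assert demux_read(comp, tags, primers, sheet0) is FailureClass.tag_absent


def test_four_primer_mismatches_is_primer_fail(tags, primers, sheet0):
    v6 = _rand_v6(3)
    left = primers.left.replace("R", "G")
    # mutate 4 positions of the left primer
    broken = "TTTT" + left[4:]
    seq = "CATGCG" + broken + v6 + revcomp(primers.right) + revcomp("CGCATG")
    assert demux_read(_composite(seq), tags, primers, sheet0) is FailureClass.primer_fail


def test_three_primer_mismatches_tolerated(tags, primers, sheet0):
    v6 = _rand_v6(4)
    left = primers.left.replace("R", "G")
    broken = "TTT" + left[3:]
    assert left[:3] != "TTT"[:3]
    seq = "CATGCG" + broken + v6 + revcomp(primers.right) + revcomp("CGCATG")
    rec = demux_read(_composite(seq), tags, primers, sheet0)
    assert not isinstance(rec, FailureClass)
    assert rec.left_primer_mm == 3


def test_truncated_4nt_tag_resolves_to_3nt_tag_with_flag(tags, primers, sheet0):
    # GTA is both tag 14-v6L and the N-1 truncation of AGTA (9-v6L)
    comp = _composite(_amplicon("GTA", "CGCATG", primers, _rand_v6(5)))
    rec = demux_read(comp, tags, primers, sheet0)
    assert not isinstance(rec, FailureClass)
    assert rec.left_tag_name == "14-v6L"
    assert rec.n1_ambiguous


def test_unique_n1_truncation_classified(tags, primers, sheet0):
    # ATGCG = CATGCG minus its 5' base; not itself a valid tag
    comp = _composite(_amplicon("ATGCG", "CGCATG", primers, _rand_v6(6)))
    assert demux_read(comp, tags, primers, sheet0) is FailureClass.tag_n1_truncated


def test_extra_5prime_bases_classified(tags, primers, sheet0):
    comp = _composite(_amplicon("TTCATGCG", "CGCATG", primers, _rand_v6(7)))
    assert (
        demux_read(comp, tags, primers, sheet0) is FailureClass.extra_5prime_bases
    )


def test_pair_not_in_sheet(tags, primers, sheet0):
    # valid tags 1-v6L/1-v6R but no such sample row
    comp = _composite(_amplicon("GCAGT", "ACTGC", primers, _rand_v6(8)))
    assert demux_read(comp, tags, primers, sheet0) is FailureClass.pair_not_in_sheet


def test_orientation_involution(tags, primers, sheet0):
    """Demuxing the reverse-complemented composite with tag roles swapped
    gives the same sample assignment."""
    v6 = _rand_v6(9)
    comp = _composite(_amplicon("CATGCG", "CGCATG", primers, v6))
    swapped_tags = TagTable(
        TagEntry(name=e.name, side=("left" if e.side == "right" else "right"), seq=e.seq)
        for e in tags.entries
    )
    swapped_sheet = SampleSheet([(r, l, s) for l, r, s in sheet0.rows])
    swapped_primers = PrimerPair(left=primers.right, right=primers.left)
    rec = demux_read(
        _composite(revcomp(comp.seq)), swapped_tags, swapped_primers, swapped_sheet
    )
    assert not isinstance(rec, FailureClass)
    assert rec.sample_id == "s0"
    assert rec.interprimer_seq == revcomp(v6)


# ---------------------------------------------------------------------------
# tag-set validation


def test_left_tag_set_n1_collisions(tags):
    report = validate_tag_set(tags, "left")
    assert report.n1_collisions == ["CTA", "GTA", "TGA"]
    assert report.length_range == (3, 6)


def test_right_tag_set_has_no_collisions(tags):
    assert validate_tag_set(tags, "right").n1_collisions == []


def test_all_bases_present_at_first_four_left_positions(tags):
    report = validate_tag_set(tags, "left")
    assert report.balanced_first_four
    for base in "ACGT":
        assert set(report.base_balance[base]) >= {1, 2, 3, 4}


def test_single_tag_set_balance():
    table = TagTable([TagEntry(name="x", side="left", seq="ACGT")])
    report = validate_tag_set(table, "left")
    assert report.n1_collisions == []
    marks = sum(len(v) for v in report.base_balance.values())
    assert marks == 4  # one base at each of the four positions


# ---------------------------------------------------------------------------
# primer coverage


def _ref_with(site: str, seed: int = 0) -> SequenceRecord:
    rng = random.Random(seed)
    pad = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    return SequenceRecord(id=f"ref{seed}", seq=pad(30) + site + pad(30))


def test_degenerate_position_matches_both_realizations(primers):
    for r_base in "AG":
        ref = _ref_with(primers.left.replace("R", r_base))
        per_ref, (matched, total) = primer_coverage([ref], primers.left)
        assert matched == total == 1


def test_anchor_mismatch_rejects_even_when_rest_is_perfect(primers):
    site = primers.left.replace("R", "A")
    mutated = site[:-3] + ("A" if site[-3] != "A" else "C") + site[-2:]
    per_ref, _ = primer_coverage([_ref_with(mutated, 1)], primers.left)
    assert per_ref == {"ref1": False}


def test_non_anchor_mismatch_budget(primers):
    site = list(primers.left.replace("R", "A"))
    # mutate 3 positions outside the 3' 5-mer anchor
    for i in (0, 3, 7):
        site[i] = "A" if site[i] != "A" else "C"
    ref = _ref_with("".join(site), 2)
    _, (m2, _) = primer_coverage([ref], primers.left, max_mm=2)
    _, (m3, _) = primer_coverage([ref], primers.left, max_mm=3)
    assert (m2, m3) == (0, 1)


def test_right_primer_found_as_revcomp(primers):
    ref = _ref_with(revcomp(primers.right), 3)
    _, (matched, _) = primer_coverage([ref], primers.right, as_revcomp=True)
    assert matched == 1


def test_anchor_longer_than_primer_errors(primers):
    with pytest.raises(ValueError):
        primer_coverage([], primers.left, anchor_len=100)


# ---------------------------------------------------------------------------
# run-level behaviour


def test_noise_free_run_demuxes_to_manifest_samples(clean_chain):
    truth = clean_chain.manifest.by_id()
    assert clean_chain.demux_stats.n_assigned == len(clean_chain.composites)
    assert all(
        truth[r.read_id].sample_id == r.sample_id for r in clean_chain.records
    )


def test_failure_classes_partition_rejects(noisy_chain):
    s = noisy_chain.demux_stats
    assert s.n_assigned + sum(s.failures.values()) == s.n_input


def test_n1_truncated_reads_classified_per_manifest(fixture6, tags, primers):
    """N-1 truncation of a collision-free tag lands in tag_n1_truncated."""
    communities, sheet = fixture6
    cfg = SimConfig(
        n_reads=300, pcr_error_rate=0.0, sequencing_errors=False,
        tag_n1_rate={"5-v6R": 0.4}, seed=55,
    )
    r1, r2, manifest = simulate_run(communities, sheet, tags, primers, cfg)
    from v6prof.merge import merge_run

    composites, _ = merge_run(zip(r1, r2))
    records, stats = demux_run(composites, tags, primers, sheet)
    n_truncated_truth = sum(
        r.right_tag_truncated or r.left_tag_truncated for r in manifest.reads
    )
    assert stats.failures[FailureClass.tag_n1_truncated] == n_truncated_truth
    assigned_ids = {r.read_id for r in records}
    for r in manifest.reads:
        assert (r.read_id in assigned_ids) == (
            not (r.left_tag_truncated or r.right_tag_truncated)
        )
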
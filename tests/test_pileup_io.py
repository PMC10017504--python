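"""Pileup and count-table behavior, checked against an independent replay oracle."""

import random
import re

import pytest

from bidseq.pileup_io import (
    CountTable,
    ReferenceSet,
    SiteCount,
    extract_motif,
    load_reference,
    pileup_deletions,
    read_count_table,
    write_count_table,
)

from conftest import SIMPLE_SEQ, write_fasta, write_sam


# ---------------------------------------------------------------------------
# references and motifs

class TestReference:
    def test_load_and_lookup(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", {"r1": "AGUGA"})
        ref = load_reference(path)
        assert ref.length("r1") == 5
        assert ref.base("r1", 2) == "U"

    def test_t_normalized_to_u(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", {"r1": "AGTGA"})
        ref = load_reference(path)
        assert ref.base("r1", 2) == "U"

    def test_duplicate_names_rejected(self, tmp_path):
        with open(tmp_path / "r.fa", "w") as fh:
            fh.write(">r1\nACGT\n>r1\nGGGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_reference(tmp_path / "r.fa")

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "r.fa").write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_reference(tmp_path / "r.fa")

    def test_out_of_bounds_position(self):
        ref = ReferenceSet({"r1": "AGUGA"})
        with pytest.raises(IndexError):
            ref.base("r1", 5)


class TestMotif:
    @pytest.mark.parametrize(
        "pos, expected",
        [(2, "AGUGA"), (0, "NNAGU"), (4, "UGANN"), (1, "NAGUG")],
    )
    def test_padding(self, pos, expected):
        ref = ReferenceSet({"r1": "AGUGA"})
        assert extract_motif(ref, "r1", pos) == expected

    def test_probe_motif_at_center(self):
        # 30-mer probe carrying the AGUGA context around its central uridine
        probe = "C" * 12 + "AGTGA" + "C" * 13
        ref = ReferenceSet({"probe": probe})
        assert extract_motif(ref, "probe", 14) == "AGUGA"
        assert ref.base("probe", 14) == "U"


# ---------------------------------------------------------------------------
# site counts and tables

class TestSiteCount:
    def test_invariants(self):
        with pytest.raises(ValueError, match="del_count"):
            SiteCount("r1", 0, "U", 5, 7, "AGUGA")
        with pytest.raises(ValueError, match="5-mer"):
            SiteCount("r1", 0, "U", 5, 1, "AGU")
        with pytest.raises(ValueError, match="center"):
            SiteCount("r1", 0, "U", 5, 1, "AGAGA")

    def test_rate(self):
        assert SiteCount("r1", 10, "U", 100, 6, "AGUGA").rate == pytest.approx(0.06)


class TestCountTableIO:
    def test_single_row_round_trip(self, tmp_path):
        t = CountTable.from_records(
            [SiteCount("r1", 10, "U", 100, 6, "AGUGA", "treated")]
        )
        write_count_table(t, tmp_path / "t.tsv")
        back = read_count_table(tmp_path / "t.tsv")
        assert back == t
        assert back.lookup("r1", 10).rate == pytest.approx(0.06)

    def test_invariant_violation_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text(
            "ref_name\tpos\tref_base\tcoverage\tdel_count\tmotif5\tlibrary_label\n"
            "r1\t10\tU\t5\t7\tAGUGA\ttreated\n"
        )
        with pytest.raises(ValueError, match="del_count"):
            read_count_table(tmp_path / "bad.tsv")

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("ref_name\tpos\nr1\t10\n")
        with pytest.raises(ValueError):
            read_count_table(tmp_path / "bad.tsv")

    def test_duplicate_position_rejected(self):
        recs = [
            SiteCount("r1", 10, "U", 100, 6, "AGUGA"),
            SiteCount("r1", 10, "U", 50, 1, "AGUGA"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            CountTable.from_records(recs)

    def test_large_random_round_trip(self, tmp_path):
        rnd = random.Random(42)
        bases = "ACGU"
        recs = []
        for i in range(1000):
            cov = rnd.randint(1, 10000)
            base = rnd.choice(bases)
            motif = (rnd.choice(bases) + rnd.choice(bases) + base
                     + rnd.choice(bases) + rnd.choice(bases))
            recs.append(
                SiteCount(f"ref{i % 7}", i, base, cov, rnd.randint(0, cov),
                          motif, rnd.choice(["treated", "input"]))
            )
        t = CountTable.from_records(recs)
        write_count_table(t, tmp_path / "t.tsv")
        assert read_count_table(tmp_path / "t.tsv") == t


# ---------------------------------------------------------------------------
# pileup against hand-walked examples

class TestPileupExamples:
    def test_internal_deletion_counted(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 0, 60, "10M1D10M")])
        t = pileup_deletions(sam, simple_reference, min_flank=2)
        assert len(t) == 21
        for pos in range(21):
            site = t.lookup("r1", pos)
            assert site.coverage == 1
            assert site.del_count == (1 if pos == 10 else 0)

    def test_no_deletion(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 0, 60, "21M")])
        t = pileup_deletions(sam, simple_reference, min_flank=2)
        assert all(s.del_count == 0 for s in t)
        assert all(s.coverage == 1 for s in t)

    def test_end_proximal_deletion_ignored_but_covered(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 0, 60, "1M1D19M")])
        t = pileup_deletions(sam, simple_reference, min_flank=2)
        assert t.lookup("r1", 1).del_count == 0
        assert t.lookup("r1", 1).coverage == 1

    def test_multibase_deletion_counts_each_position(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 0, 60, "9M2D9M")])
        t = pileup_deletions(sam, simple_reference, min_flank=2)
        assert t.lookup("r1", 9).del_count == 1
        assert t.lookup("r1", 10).del_count == 1

    def test_insertions_and_clips_do_not_count(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 5, 60, "3S5M2I5M4S")])
        t = pileup_deletions(sam, simple_reference, min_flank=2)
        assert len(t) == 10  # 5M + 5M reference bases
        assert all(s.del_count == 0 for s in t)

    def test_secondary_and_unmapped_skipped(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 0, 60, "21M"),
                         ("q2", 256, "r1", 0, 60, "21M"),
                         ("q3", 4, "r1", 0, 60, "21M"),
                         ("q4", 2048, "r1", 0, 60, "21M")])
        t = pileup_deletions(sam, simple_reference)
        assert t.lookup("r1", 0).coverage == 1

    def test_mapq_floor(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 0, 5, "21M")])
        assert len(pileup_deletions(sam, simple_reference, mapq_min=10)) == 0
        assert len(pileup_deletions(sam, simple_reference, mapq_min=0)) == 21

    def test_unknown_reference_rejected(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"rX": 21},
                        [("q1", 0, "rX", 0, 60, "21M")])
        with pytest.raises(ValueError, match="unknown reference"):
            pileup_deletions(sam, simple_reference)

    def test_cigar_past_reference_end_rejected(self, tmp_path, simple_reference):
        sam = write_sam(tmp_path / "a.sam", {"r1": 21},
                        [("q1", 0, "r1", 10, 60, "15M")])
        with pytest.raises(ValueError, match="runs past"):
            pileup_deletions(sam, simple_reference)


# ---------------------------------------------------------------------------
# replay oracle on random instances

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _oracle_pileup(sam_path, ref_len, min_flank):
    """Independent per-read replay: classify every reference position of every
    read as aligned or deleted, then apply the flank rule by counting aligned
    positions on either side of each deleted one."""
    cov = [0] * ref_len
    dels = [0] * ref_len
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.split("\t")
            flag = int(f[1])
            if flag & (0x4 | 0x100 | 0x800):
                continue
            pos = int(f[3]) - 1
            aligned, deleted = [], []
            for n, op in _CIGAR_RE.findall(f[5]):
                n = int(n)
                if op in "M=X":
                    aligned.extend(range(pos, pos + n))
                    pos += n
                elif op == "D":
                    deleted.extend(range(pos, pos + n))
                    pos += n
                elif op == "N":
                    pos += n
            for p in aligned + deleted:
                cov[p] += 1
            for p in deleted:
                left = sum(1 for a in aligned if a < p)
                right = sum(1 for a in aligned if a > p)
                if left >= min_flank and right >= min_flank:
                    dels[p] += 1
    return cov, dels


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("min_flank", [0, 2])
def test_pileup_matches_replay_oracle(tmp_path, seed, min_flank):
    """On random <=50-read alignments the streaming pileup agrees with a naive
    position-set replay, including the conservation identity."""
    rnd = random.Random(seed)
    ref_len = 60
    seq = "".join(rnd.choice("ACGT") for _ in range(ref_len))
    ref = ReferenceSet({"r": seq})
    reads = []
    for i in range(rnd.randint(1, 50)):
        ops = []
        # random alternation of M/D/I/S segments, M not guaranteed at ends
        for _ in range(rnd.randint(1, 5)):
            kind = rnd.choices("MDIS", weights=[6, 3, 1, 1])[0]
            ops.append((kind, rnd.randint(1, 5)))
        ref_span = sum(n for k, n in ops if k in "MD")
        if ref_span == 0 or ref_span > ref_len:
            continue
        start = rnd.randint(0, ref_len - ref_span)
        cigar = "".join(f"{n}{k}" for k, n in ops)
        reads.append((f"q{i}", 0, "r", start, 60, cigar))
    if not reads:
        reads = [("q0", 0, "r", 0, 60, "10M")]
    sam = write_sam(tmp_path / "r.sam", {"r": ref_len}, reads)

    table = pileup_deletions(sam, ref, min_flank=min_flank)
    cov, dels = _oracle_pileup(sam, ref_len, min_flank)
    for p in range(ref_len):
        site = table.lookup("r", p)
        assert (site.coverage if site else 0) == cov[p]
        assert (site.del_count if site else 0) == dels[p]


def test_removing_a_read_never_increases_counts(tmp_path, simple_reference):
    reads = [("q1", 0, "r1", 0, 60, "10M1D10M"),
             ("q2", 0, "r1", 2, 60, "19M"),
             ("q3", 0, "r1", 5, 60, "5M1D10M")]
    full = pileup_deletions(
        write_sam(tmp_path / "full.sam", {"r1": 21}, reads), simple_reference
    )
    reduced = pileup_deletions(
        write_sam(tmp_path / "red.sam", {"r1": 21}, reads[:-1]), simple_reference
    )
    for pos in range(21):
        f = full.lookup("r1", pos)
        r = reduced.lookup("r1", pos)
        assert (r.coverage if r else 0) <= (f.coverage if f else 0)
        assert (r.del_count if r else 0) <= (f.del_count if f else 0)
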
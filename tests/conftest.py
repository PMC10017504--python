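import pytest

from bidseq.pileup_io import ReferenceSet


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_sam(path, ref_lengths, reads):
    """Write a minimal SAM file.

    ``reads``: iterable of (qname, flag, ref, pos0, mapq, cigar).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for name, ln in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for qname, flag, ref, pos0, mapq, cigar in reads:
            fh.write(
                f"{qname}\t{flag}\t{ref}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\n"
            )
    return path


# 21-mer with a single uridine at position 10, motif AGUGA (T alphabet on
# purpose: the reference reader must normalize T to U)
SIMPLE_SEQ = "A" * 8 + "AGTGA" + "A" * 8


@pytest.fixture
def simple_reference():
    return ReferenceSet({"r1": SIMPLE_SEQ})
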
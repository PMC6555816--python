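"""Packaged tau repeat-domain sequence and residue bookkeeping.

All residue numbers in this package are absolute, 1-based positions in the
2N4R (441-residue) isoform of human tau.  The repeat domain (tau RD)
construct spans residues 244-380; the PHF6 amyloid motif VQIVYK sits at
306-311.
"""
from __future__ import annotations

from importlib import resources

from Bio import SeqIO

TAU_RD_START = 244
TAU_RD_END = 380

#: leading 11-mer of repeat 2 entering VQIVYK (residues 295-305)
R2_LEADING = "DNIKHVPGGGS"
#: leading 11-mer of repeat 1, the 3R-isoform analogue (residues 264-274)
R1_LEADING = "ENLKHQPGGGK"
#: PHF6 hexapeptide amyloid motif (residues 306-311)
VQIVYK_CORE = "VQIVYK"


def tau_rd_sequence() -> str:
    """Return the packaged tau RD (244-380) amino-acid sequence."""
    ref = resources.files("taushield.data") / "tau_rd_244_380.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def residue_at(position: int) -> str:
    """One-letter residue at an absolute 2N4R position within tau RD."""
    seq = tau_rd_sequence()
    if not TAU_RD_START <= position <= TAU_RD_END:
        raise ValueError(f"position {position} outside tau RD {TAU_RD_START}-{TAU_RD_END}")
    return seq[position - TAU_RD_START]


def lysine_positions() -> list[int]:
    """Absolute positions of all lysines in tau RD, the DSS-reactive sites."""
    seq = tau_rd_sequence()
    return [TAU_RD_START + i for i, aa in enumerate(seq) if aa == "K"]
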
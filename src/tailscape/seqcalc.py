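"""Sequence-derived quantities: extinction coefficients and residue counts.

Protein ε280 uses the classical chromophore sum (5500 Trp, 1490 Tyr,
125 per cystine pair); cysteines are treated as reduced by default, which
is the right choice for Zn-coordinating or DTT-containing preparations.

Single-stranded DNA ε260 uses the Cantor–Warshaw–Shapiro nearest-neighbor
model (pair sums minus internal monomers). Duplex ε260 applies base-pair-
fraction hypochromicity in the Tataurov–You–Owczarzy form used by vendor
UV calculators::

    ε_duplex = (1 - h) · (ε_top + ε_bottom),   h = 0.287·f_AT + 0.059·f_GC
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinSeq", "DNADuplex",
    "protein_e280", "ss_dna_e260", "duplex_e260", "count_non_proline",
    "reverse_complement", "read_fasta", "write_fasta",
    "H3_TAIL_1_44", "DNA_21MER_TOP", "DNA_21MER_BOTTOM", "WIDOM_601_147",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGT")

# molar extinction coefficients at 280 nm, M^-1 cm^-1
EPS_TRP = 5500.0
EPS_TYR = 1490.0
EPS_CYSTINE = 125.0

# Cantor–Warshaw–Shapiro nearest-neighbor ε260 (M^-1 cm^-1)
NN_PAIR_E260 = {
    "AA": 27400, "AC": 21200, "AG": 25000, "AT": 22800,
    "CA": 21200, "CC": 14600, "CG": 18000, "CT": 15200,
    "GA": 25200, "GC": 17600, "GG": 21600, "GT": 20000,
    "TA": 23400, "TC": 16200, "TG": 19000, "TT": 16800,
}
MONO_E260 = {"A": 15400, "C": 7400, "G": 11500, "T": 8700}

# hypochromicity coefficients (fraction of summed single-strand absorbance
# lost on duplex formation, per AT / GC base-pair fraction)
HYPO_AT = 0.287
HYPO_GC = 0.059

# --- sequences printed in the study this package accompanies -------------
#: H3 N-terminal tail, residues 1-44 (the native Y41 is the chromophore)
H3_TAIL_1_44 = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPG"
#: 21-bp duplex used for tail/DNA binding work
DNA_21MER_TOP = "CTCAATTGGTCGTAGACAGCT"
DNA_21MER_BOTTOM = "AGCTGTCTACGACCAATTGAG"
#: 147-bp Widom 601 nucleosome-positioning sequence (top strand)
WIDOM_601_147 = (
    "ATCGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACG"
    "TACGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGAT"
    "ATATACATCCGAT"
)


def _validate_protein(seq: str) -> str:
    seq = seq.upper().replace(" ", "")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letter(s): {sorted(bad)}")
    return seq


def _validate_dna(seq: str) -> str:
    seq = seq.upper().replace(" ", "")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA base(s): {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(_validate_dna(seq)).reverse_complement())


@dataclass(frozen=True)
class ProteinSeq:
    sequence: str
    reduced: bool = True

    def __post_init__(self):
        object.__setattr__(self, "sequence", _validate_protein(self.sequence))


@dataclass(frozen=True)
class DNADuplex:
    top: str
    bottom: str | None = None

    def __post_init__(self):
        top = _validate_dna(self.top)
        bottom = (reverse_complement(top) if self.bottom is None
                  else _validate_dna(self.bottom))
        if reverse_complement(top) != bottom:
            raise ValueError("strands are not reverse-complementary")
        object.__setattr__(self, "top", top)
        object.__setattr__(self, "bottom", bottom)

    @property
    def f_at(self) -> float:
        return sum(1 for b in self.top if b in "AT") / len(self.top)

    @property
    def f_gc(self) -> float:
        return 1.0 - self.f_at


def protein_e280(seq) -> float:
    """ε280 in M⁻¹cm⁻¹ from Trp/Tyr/cystine counts.

    ``seq`` may be a string or a ProteinSeq; reduced (free-thiol) cysteines
    contribute nothing, and pairing into cystines is only assumed when
    ``reduced=False``.
    """
    ps = seq if isinstance(seq, ProteinSeq) else ProteinSeq(seq)
    s = ps.sequence
    n_cystine = 0 if ps.reduced else s.count("C") // 2
    return (EPS_TRP * s.count("W") + EPS_TYR * s.count("Y")
            + EPS_CYSTINE * n_cystine)


def ss_dna_e260(strand: str, allow_monomer: bool = False) -> float:
    """Single-strand ε260: Σ nearest-neighbor pairs − Σ internal monomers."""
    s = _validate_dna(strand)
    if len(s) < 2:
        if len(s) == 1 and allow_monomer:
            return float(MONO_E260[s])
        raise ValueError("nearest-neighbor model needs length >= 2 "
                         "(pass allow_monomer=True for single bases)")
    pairs = sum(NN_PAIR_E260[s[i:i + 2]] for i in range(len(s) - 1))
    internal = sum(MONO_E260[b] for b in s[1:-1])
    return float(pairs - internal)


def duplex_e260(duplex) -> float:
    """Duplex ε260 with base-pair-fraction hypochromicity.

    ``duplex`` may be a DNADuplex, a top-strand string (bottom inferred as
    the reverse complement), or a (top, bottom) pair.
    """
    if isinstance(duplex, DNADuplex):
        d = duplex
    elif isinstance(duplex, str):
        d = DNADuplex(duplex)
    else:
        d = DNADuplex(*duplex)
    h = HYPO_AT * d.f_at + HYPO_GC * d.f_gc
    return (1.0 - h) * (ss_dna_e260(d.top) + ss_dna_e260(d.bottom))


def count_non_proline(seq) -> int:
    """Number of residues other than proline (upper bound on the backbone
    amide peaks observable in an ¹H-¹⁵N correlation spectrum)."""
    ps = seq if isinstance(seq, ProteinSeq) else ProteinSeq(seq)
    return sum(1 for c in ps.sequence if c != "P")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
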
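"""Per-codon translation-speed weights from tRNA pools, and codon-usage profiles.

The central quantity is the per-codon relative adaptiveness ``w`` (the codon's
tAI): a codon is fast when the tRNAs that decode it are abundant (high gene copy
number, tGCN) and pair well (low wobble selective constraint ``s``).  The
absolute adaptiveness of codon *i* is

    W_i = sum_j (1 - s_ij) * tGCN_j

over the anticodons *j* that can decode *i* (Watson-Crick plus one wobble
pairing at the third position), and ``w_i = W_i / max_i W_i``.  Codons whose
tRNA set is empty under these rules (AUA with the bundled E. coli table) are
imputed with the geometric mean of the non-zero weights.  The CGA codon, read
only through a very inefficient I:A wobble, receives a fixed override weight
(default 0.1333) so its reciprocal time does not dominate every downstream
average.

A gene's tAI is the geometric mean of its codons' ``w``; ``1/w`` is treated as
the codon's translation time, which is what the bottleneck scan averages.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_rna_by_id

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "DEFAULT_S_VALUES",
    "DEFAULT_CGA_WEIGHT",
    "TRNAPool",
    "CodonWeightTable",
    "CodingSequence",
    "CodonUsageProfile",
    "ExpressionLevelMap",
    "InvalidSequenceError",
    "WeightComputationError",
    "compute_weights",
    "gene_tai",
    "time_profile",
    "genome_codon_usage",
    "transcriptome_codon_usage",
]

_TABLE = unambiguous_rna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AA_TO_CODONS
}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Decoding rules at the codon third position: each codon is read by its
#: Watson-Crick anticodon and by one wobble anticodon.  Keys of the pairing
#: class are "<codon third base>:<anticodon wobble base>", A34 being treated
#: as inosine (I) against C- and A-ending codons.
_THIRD_POSITION_PAIRINGS: dict[str, tuple[tuple[str, str], ...]] = {
    "U": (("A", "U:A"), ("G", "U:G")),
    "C": (("G", "C:G"), ("A", "C:I")),
    "A": (("U", "A:U"), ("A", "A:I")),
    "G": (("C", "G:C"), ("U", "G:U")),
}

DEFAULT_S_VALUES: dict[str, float] = {
    "U:A": 0.0,
    "C:G": 0.0,
    "A:U": 0.0,
    "G:C": 0.0,
    "U:G": 0.41,
    "C:I": 0.28,
    "A:I": 0.9999,
    "G:U": 0.68,
}

DEFAULT_CGA_WEIGHT = 0.1333


class InvalidSequenceError(ValueError):
    """A nucleotide sequence cannot be interpreted as an in-frame ORF."""


class WeightComputationError(ValueError):
    """The tRNA pool cannot yield a full 61-codon weight table."""


def reverse_complement(rna: str) -> str:
    return rna.translate(_RNA_COMPLEMENT)[::-1]


def _normalize_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class TRNAPool:
    """A tRNA repertoire: anticodon gene copy numbers plus wobble s-values.

    Parameters
    ----------
    entries
        ``(anticodon, gene_copy_number)`` pairs; anticodons are 3-letter RNA
        strings written 5'->3' and must be unique.
    s_values
        Map from pairing class (see :data:`DEFAULT_S_VALUES`) to the
        selective constraint ``s`` in [0, 1].
    """

    entries: tuple[tuple[str, int], ...]
    s_values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_S_VALUES))

    def __post_init__(self) -> None:
        seen: set[str] = set()
        normalized = []
        for anticodon, gcn in self.entries:
            ac = _normalize_rna(anticodon)
            if len(ac) != 3 or any(b not in "ACGU" for b in ac):
                raise ValueError(f"malformed anticodon {anticodon!r}")
            if ac in seen:
                raise ValueError(f"anticodon {ac} listed more than once")
            if gcn < 0:
                raise ValueError(f"negative gene copy number for anticodon {ac}")
            seen.add(ac)
            normalized.append((ac, int(gcn)))
        object.__setattr__(self, "entries", tuple(normalized))
        for cls, s in self.s_values.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"s-value for class {cls} outside [0, 1]: {s}")

    @property
    def copies(self) -> dict[str, int]:
        return dict(self.entries)


@dataclass(frozen=True)
class CodonWeightTable:
    """Relative adaptiveness ``w`` for all 61 sense codons (max-normalized)."""

    w: Mapping[str, float]
    source: str = ""
    cga_override: bool = False

    def __post_init__(self) -> None:
        keys = set(self.w)
        if keys != set(SENSE_CODONS):
            missing = set(SENSE_CODONS) - keys
            extra = keys - set(SENSE_CODONS)
            raise ValueError(
                f"weight table must cover exactly the 61 sense codons "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for codon, value in self.w.items():
            if not (value > 0.0):
                raise ValueError(f"non-positive weight for codon {codon}: {value}")
        object.__setattr__(self, "w", dict(self.w))

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]

    def times(self) -> dict[str, float]:
        """Per-codon translation time 1/w."""
        return {c: 1.0 / v for c, v in self.w.items()}


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame ORF as an ordered list of sense codons (stop excluded)."""

    id: str
    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise InvalidSequenceError(f"gene {self.id!r}: empty codon list")
        bad = [c for c in self.codons if c not in CODON_TO_AA]
        if bad:
            raise InvalidSequenceError(
                f"gene {self.id!r}: non-sense codon(s) {bad[:3]}"
            )
        object.__setattr__(self, "codons", tuple(self.codons))

    @property
    def length_l(self) -> int:
        return len(self.codons)

    @classmethod
    def from_nucleotides(cls, gene_id: str, sequence: str) -> "CodingSequence":
        """Parse an ORF nucleotide string (DNA or RNA) into codons.

        The sequence must be a multiple of 3, unambiguous A/C/G/U(T), with no
        internal stop codons; a single trailing stop codon is removed.
        """
        seq = _normalize_rna(sequence)
        if len(seq) % 3 != 0:
            raise InvalidSequenceError(
                f"gene {gene_id!r}: length {len(seq)} nt is not a multiple of 3"
            )
        bad_chars = sorted(set(seq) - set("ACGU"))
        if bad_chars:
            raise InvalidSequenceError(
                f"gene {gene_id!r}: ambiguous or invalid characters {bad_chars}"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        internal = [i + 1 for i, c in enumerate(codons) if c in STOP_CODONS]
        if internal:
            raise InvalidSequenceError(
                f"gene {gene_id!r}: internal stop codon at codon position(s) {internal[:3]}"
            )
        if not codons:
            raise InvalidSequenceError(f"gene {gene_id!r}: no sense codons")
        return cls(id=gene_id, codons=tuple(codons))

    def translate(self) -> str:
        return "".join(CODON_TO_AA[c] for c in self.codons)

    def to_nucleotides(self) -> str:
        return "".join(self.codons)


@dataclass(frozen=True)
class CodonUsageProfile:
    """Normalized 61-codon frequency vector with its raw counts."""

    freq: Mapping[str, float]
    scope: str  # "genome" | "transcriptome" | "single-gene"
    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.freq) != set(SENSE_CODONS):
            raise ValueError("usage profile must cover exactly the 61 sense codons")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"codon fractions sum to {total}, not 1")
        object.__setattr__(self, "freq", dict(self.freq))
        object.__setattr__(self, "counts", dict(self.counts))


@dataclass(frozen=True)
class ExpressionLevelMap:
    """Gene id -> mRNA level (non-negative, arbitrary units).

    Genes absent from the map are treated as having zero mRNA by the
    transcriptome weighting (the explicit zero-imputation policy).
    """

    levels: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, level in self.levels.items():
            if level < 0:
                raise ValueError(f"negative mRNA level for gene {gene!r}")
        object.__setattr__(self, "levels", dict(self.levels))

    def get(self, gene_id: str) -> float:
        return self.levels.get(gene_id, 0.0)


def _decoding_terms(codon: str, pool: TRNAPool) -> list[tuple[str, str, int, float]]:
    """(anticodon, pairing class, tGCN, s) terms contributing to a codon's W."""
    copies = pool.copies
    terms = []
    for wobble_base, cls in _THIRD_POSITION_PAIRINGS[codon[2]]:
        anticodon = wobble_base + reverse_complement(codon[:2])
        gcn = copies.get(anticodon, 0)
        s = pool.s_values.get(cls)
        if s is None:
            raise WeightComputationError(f"no s-value for pairing class {cls}")
        terms.append((anticodon, cls, gcn, s))
    return terms


def compute_weights(
    pool: TRNAPool,
    cga_weight: float | None = DEFAULT_CGA_WEIGHT,
    impute_zero: bool = True,
    source: str = "computed from tRNA pool",
) -> CodonWeightTable:
    """Build the 61-codon relative-adaptiveness table from a tRNA pool.

    ``W_i = sum_j (1 - s_ij) * tGCN_j`` over decoding anticodons, normalized
    to a maximum of 1.  When ``cga_weight`` is not None, CGA's weight is set
    to that value after normalization (default 0.1333); the override is
    applied before imputation so CGA's degenerate computed weight never
    enters the imputation mean.  Zero-``W`` codons are then imputed with the
    geometric mean of the non-zero weights when ``impute_zero`` is true,
    otherwise an error names the offending codon.
    """
    if not pool.entries or all(gcn == 0 for _, gcn in pool.entries):
        raise WeightComputationError("empty tRNA pool: no anticodon copies")
    if cga_weight is not None and not (0.0 < cga_weight <= 1.0):
        raise ValueError(f"cga_weight must be in (0, 1], got {cga_weight}")

    absolute = {
        codon: sum((1.0 - s) * gcn for _, _, gcn, s in _decoding_terms(codon, pool))
        for codon in SENSE_CODONS
    }
    w_max = max(absolute.values())
    if w_max <= 0:
        raise WeightComputationError("all codon adaptiveness values are zero")
    w = {codon: value / w_max for codon, value in absolute.items()}

    if cga_weight is not None:
        w["CGA"] = cga_weight
    to_impute = [c for c in SENSE_CODONS if w[c] == 0.0]
    if to_impute:
        if not impute_zero:
            raise WeightComputationError(
                f"codon(s) {to_impute} have zero adaptiveness and imputation is disabled"
            )
        nonzero = [v for v in w.values() if v > 0.0]
        geo_mean = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
        for codon in to_impute:
            w[codon] = geo_mean
    return CodonWeightTable(w=w, source=source, cga_override=cga_weight is not None)


def gene_tai(seq: CodingSequence, weights: CodonWeightTable) -> float:
    """Gene-level tAI: geometric mean of the per-codon weights."""
    logs = np.log([weights[c] for c in seq.codons])
    return float(np.exp(logs.mean()))


def time_profile(seq: CodingSequence, weights: CodonWeightTable) -> np.ndarray:
    """Per-codon translation times 1/w along the gene (length ``length_l``)."""
    return 1.0 / np.array([weights[c] for c in seq.codons], dtype=float)


def _tally(orfs: Iterable[CodingSequence]) -> Counter:
    counts: Counter = Counter()
    for orf in orfs:
        counts.update(orf.codons)
    return counts


def genome_codon_usage(orfs: Sequence[CodingSequence]) -> CodonUsageProfile:
    """Codon usage over a set of ORFs: pooled counts / total codon count."""
    if not orfs:
        raise ValueError("genome codon usage requires at least one ORF")
    counts = _tally(orfs)
    total = sum(counts.values())
    freq = {c: counts.get(c, 0) / total for c in SENSE_CODONS}
    return CodonUsageProfile(
        freq=freq, scope="genome", counts={c: float(counts.get(c, 0)) for c in SENSE_CODONS}
    )


def transcriptome_codon_usage(
    orfs: Sequence[CodingSequence],
    expr: ExpressionLevelMap,
    per_gene_frequencies: bool = False,
) -> CodonUsageProfile:
    """mRNA-weighted codon usage.

    Each gene contributes its codon counts multiplied by its mRNA level;
    contributions are summed per codon and divided by the weighted codon
    total.  Genes absent from ``expr`` contribute zero.  With
    ``per_gene_frequencies`` the per-gene codon *fractions* are weighted
    instead of the raw counts (so gene length does not matter).
    """
    if not orfs:
        raise ValueError("transcriptome codon usage requires at least one ORF")
    weighted: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
    total = 0.0
    any_positive = False
    for orf in orfs:
        level = expr.get(orf.id)
        if level <= 0:
            continue
        any_positive = True
        gene_counts = Counter(orf.codons)
        denom = orf.length_l if per_gene_frequencies else 1.0
        for codon, count in gene_counts.items():
            weighted[codon] += level * count / denom
        total += level * (1.0 if per_gene_frequencies else orf.length_l)
    if not any_positive:
        raise ValueError("all mRNA levels are zero for the provided ORFs")
    freq = {c: weighted[c] / total for c in SENSE_CODONS}
    return CodonUsageProfile(freq=freq, scope="transcriptome", counts=weighted)
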
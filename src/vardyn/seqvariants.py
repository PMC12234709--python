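"""Exhaustive enumeration of SNV-reachable missense variants of a coding sequence.

Every single-nucleotide substitution of a spliced coding sequence (cDNA CDS)
is classified at the protein level; substitutions whose only effect is an
amino-acid exchange (no stop gained or lost, start codon intact) form the
missense set. Distinct nucleotide changes that induce the same protein change
are collapsed by default, with the contributing nucleotide substitutions kept
as provenance.

Coordinates are 1-based on both the CDS and the protein, matching the
clinical ``p.<ref><pos><alt>`` notation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
STOP = "*"


class EffectClass(str, Enum):
    """Protein-level effect of a single-nucleotide substitution."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"


@dataclass(frozen=True)
class CodingSequence:
    """A spliced coding sequence starting at the initiator codon.

    Parameters
    ----------
    id : str
        Accession-like identifier.
    nucleotides : str
        Sequence over {A, C, G, T}; length must be a multiple of 3.
    codon_table : int
        NCBI genetic-code table identifier (1 = standard).
    """

    id: str
    nucleotides: str
    codon_table: int = 1

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError("coding sequence length must be a positive multiple of 3")
        if set(seq) - set(NUCLEOTIDES):
            raise ValueError("coding sequence restricted to ACGT alphabet")

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codon(self, codon_index: int) -> str:
        """Return the 1-based ``codon_index``-th codon."""
        if not 1 <= codon_index <= self.n_codons:
            raise ValueError(f"codon index {codon_index} out of range")
        return self.nucleotides[(codon_index - 1) * 3 : codon_index * 3]

    def protein(self, trim_stop: bool = True) -> str:
        """Translate the full CDS; terminal stop trimmed by default."""
        aa = str(Seq(self.nucleotides).translate(table=self.codon_table))
        if trim_stop and aa.endswith(STOP):
            aa = aa[:-1]
        return aa


@dataclass(frozen=True)
class MissenseVariant:
    """A protein-level amino-acid exchange reachable by one nucleotide change."""

    cds_position: int
    ref_nt: str
    alt_nt: str
    codon_index: int
    ref_aa: str
    alt_aa: str
    protein_notation: str
    # all (cds_position, ref_nt, alt_nt) triples producing this protein change
    nucleotide_changes: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.ref_nt == self.alt_nt:
            raise ValueError("ref and alt nucleotides must differ")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")
        if STOP in (self.ref_aa, self.alt_aa):
            raise ValueError("missense variants cannot involve a stop symbol")
        if self.codon_index != (self.cds_position + 2) // 3:
            raise ValueError("codon_index inconsistent with cds_position")


def translate_codon(codon: str, table: int = 1) -> str:
    """Translate one codon; stop codons return ``'*'``.

    Raises
    ------
    ValueError
        If the codon is not three ACGT characters.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(NUCLEOTIDES):
        raise ValueError(f"invalid codon {codon!r}")
    tbl = unambiguous_dna_by_id[table]
    if codon in tbl.stop_codons:
        return STOP
    return tbl.forward_table[codon]


def classify_substitution(cds: CodingSequence, pos: int, alt_nt: str) -> EffectClass:
    """Classify the protein-level effect of substituting ``alt_nt`` at 1-based ``pos``.

    The initiator codon losing ATG is ``start_loss``; a reference stop codon
    that no longer encodes stop is ``stop_loss``.
    """
    if not 1 <= pos <= len(cds.nucleotides):
        raise ValueError(f"position {pos} out of range")
    alt_nt = alt_nt.upper()
    if alt_nt not in NUCLEOTIDES:
        raise ValueError(f"invalid nucleotide {alt_nt!r}")
    ref_nt = cds.nucleotides[pos - 1]
    if alt_nt == ref_nt:
        raise ValueError("alt nucleotide equals the reference")

    codon_index = (pos + 2) // 3
    ref_codon = cds.codon(codon_index)
    offset = (pos - 1) % 3
    alt_codon = ref_codon[:offset] + alt_nt + ref_codon[offset + 1 :]
    ref_aa = translate_codon(ref_codon, cds.codon_table)
    alt_aa = translate_codon(alt_codon, cds.codon_table)

    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        return EffectClass.START_LOSS
    if ref_aa == STOP:
        return EffectClass.SYNONYMOUS if alt_aa == STOP else EffectClass.STOP_LOSS
    if alt_aa == STOP:
        return EffectClass.STOP_GAIN
    if alt_aa == ref_aa:
        return EffectClass.SYNONYMOUS
    return EffectClass.MISSENSE


def enumerate_missense(
    cds: CodingSequence,
    dedupe_protein: bool = True,
    include_start_codon: bool = False,
) -> list[MissenseVariant]:
    """Enumerate missense variants over all 3L single-nucleotide substitutions.

    Parameters
    ----------
    dedupe_protein : bool
        Collapse distinct SNVs producing the same protein change (default),
        keeping every contributing nucleotide change as provenance.
    include_start_codon : bool
        When True, amino-acid-changing substitutions in an ATG initiator codon
        are counted as missense instead of start_loss (start-loss variants are
        functionally truncating and are excluded by default).

    Returns
    -------
    list of MissenseVariant, ordered by (codon_index, alt_aa, cds_position).
    """
    by_protein: dict[tuple, MissenseVariant] = {}
    out: list[MissenseVariant] = []
    for pos in range(1, len(cds.nucleotides) + 1):
        ref_nt = cds.nucleotides[pos - 1]
        codon_index = (pos + 2) // 3
        ref_codon = cds.codon(codon_index)
        offset = (pos - 1) % 3
        for alt_nt in NUCLEOTIDES:
            if alt_nt == ref_nt:
                continue
            effect = classify_substitution(cds, pos, alt_nt)
            if effect == EffectClass.START_LOSS and include_start_codon:
                alt_codon = ref_codon[:offset] + alt_nt + ref_codon[offset + 1 :]
                alt_aa = translate_codon(alt_codon, cds.codon_table)
                if alt_aa not in (STOP, translate_codon(ref_codon, cds.codon_table)):
                    effect = EffectClass.MISSENSE
            if effect != EffectClass.MISSENSE:
                continue
            alt_codon = ref_codon[:offset] + alt_nt + ref_codon[offset + 1 :]
            ref_aa = translate_codon(ref_codon, cds.codon_table)
            alt_aa = translate_codon(alt_codon, cds.codon_table)
            var = MissenseVariant(
                cds_position=pos,
                ref_nt=ref_nt,
                alt_nt=alt_nt,
                codon_index=codon_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                protein_notation=f"p.{ref_aa}{codon_index}{alt_aa}",
                nucleotide_changes=((pos, ref_nt, alt_nt),),
            )
            key = (codon_index, ref_aa, alt_aa)
            if dedupe_protein:
                if key in by_protein:
                    prev = by_protein[key]
                    by_protein[key] = MissenseVariant(
                        cds_position=prev.cds_position,
                        ref_nt=prev.ref_nt,
                        alt_nt=prev.alt_nt,
                        codon_index=prev.codon_index,
                        ref_aa=prev.ref_aa,
                        alt_aa=prev.alt_aa,
                        protein_notation=prev.protein_notation,
                        nucleotide_changes=prev.nucleotide_changes
                        + ((pos, ref_nt, alt_nt),),
                    )
                else:
                    by_protein[key] = var
            else:
                out.append(var)
    if dedupe_protein:
        out = list(by_protein.values())
    out.sort(key=lambda v: (v.codon_index, v.alt_aa, v.cds_position))
    return out


def classify_all(cds: CodingSequence) -> dict[EffectClass, int]:
    """Count every one of the 3L substitutions by effect class (partition)."""
    counts = {e: 0 for e in EffectClass}
    for pos in range(1, len(cds.nucleotides) + 1):
        ref_nt = cds.nucleotides[pos - 1]
        for alt_nt in NUCLEOTIDES:
            if alt_nt != ref_nt:
                counts[classify_substitution(cds, pos, alt_nt)] += 1
    return counts


def mutant_protein(cds: CodingSequence, variant: MissenseVariant) -> str:
    """Protein sequence with the variant's single substitution applied, stop trimmed."""
    protein = cds.protein(trim_stop=True)
    idx = variant.codon_index - 1
    if protein[idx] != variant.ref_aa:
        raise ValueError("variant does not match the coding sequence")
    return protein[:idx] + variant.alt_aa + protein[idx + 1 :]


def write_variant_fasta(
    cds: CodingSequence,
    variants: Iterable[MissenseVariant],
    path: str | Path,
    include_wildtype: bool = False,
) -> int:
    """Write one protein FASTA record per variant; header ``<id>|<p-notation>``.

    Returns the number of records written. An empty variant set yields a
    valid empty file (with a warning) unless ``include_wildtype`` is set.
    """
    records = []
    if include_wildtype:
        records.append(
            SeqRecord(Seq(cds.protein()), id=f"{cds.id}|wildtype", description="")
        )
    for v in variants:
        records.append(
            SeqRecord(
                Seq(mutant_protein(cds, v)),
                id=f"{cds.id}|{v.protein_notation}",
                description="",
            )
        )
    if not records:
        warnings.warn("writing an empty variant FASTA", stacklevel=2)
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")
    return len(records)


def write_variant_table(variants: Iterable[MissenseVariant], path: str | Path) -> None:
    """Write the variant set as a TSV with the standard column order."""
    cols = [
        "cds_position",
        "ref_nt",
        "alt_nt",
        "codon_index",
        "ref_aa",
        "alt_aa",
        "protein_notation",
        "effect_class",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            fh.write(
                f"{v.cds_position}\t{v.ref_nt}\t{v.alt_nt}\t{v.codon_index}\t"
                f"{v.ref_aa}\t{v.alt_aa}\t{v.protein_notation}\tmissense\n"
            )
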
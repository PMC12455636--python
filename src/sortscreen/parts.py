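"""Modular-cloning part grammar: parts, Golden Gate assembly, design-space enumeration.

The library design follows the yeast-toolkit (MoClo-style) positional grammar:
promoters occupy slot 2, signal peptides slot 3a, coding sequences slot 3b,
a C-terminal fusion module slot 4a and the anchor/terminator cassette slot 4b.
Each part carries 4-nt fusion overhangs; an assembly is valid when every
junction's overhangs agree, and the assembled sequence is scarless (each shared
4-nt junction appears exactly once).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

#: grammar slot order for a display/secretion construct
SLOT_ORDER = ("promoter", "sp_flag", "cds", "fusion_4a", "cassette_4b")

ROLES = frozenset(
    {"promoter", "sp_flag", "cds", "fusion_4a", "cassette_4b", "barcode_fwd", "barcode_rev"}
)

STRENGTH_CLASSES = frozenset({"strong", "medium", "weak"})

# One ELP unit: 100 aa of VPGXG pentapeptide repeats, guest residues V/A/G in
# the block pattern 5-2-3 repeated twice.
_ELP_UNIT_BLOCKS = (("VPGVG", 5), ("VPGAG", 2), ("VPGGG", 3)) * 2

# Fixed codon per amino acid for deterministic DNA-level ELP fixtures.
_CODON = {
    "V": "GTT",
    "P": "CCA",
    "G": "GGT",
    "A": "GCT",
}


class PartError(ValueError):
    """Raised for invalid parts, manifests or assemblies."""


@dataclass(frozen=True)
class Part:
    """One modular genetic element.

    Parameters
    ----------
    part_id : str
        Unique identifier within a registry (e.g. ``pYTK010``, ``MF``, ``CBM``).
    role : str
        Grammar slot: one of ``promoter``, ``sp_flag``, ``cds``, ``fusion_4a``,
        ``cassette_4b``, ``barcode_fwd``, ``barcode_rev``.
    sequence : str
        Uppercase DNA over {A,C,G,T}; includes the two 4-nt overhangs at its ends.
    overhang_5, overhang_3 : str
        The 4-nt fusion overhangs at the 5' and 3' end of the part body.
    strength_class : str or None
        Promoter strength bin (``strong``/``medium``/``weak``); promoters only.
    """

    part_id: str
    role: str
    sequence: str
    overhang_5: str
    overhang_3: str
    strength_class: str | None = None

    def __post_init__(self) -> None:
        if not self.part_id:
            raise PartError("part_id must be non-empty")
        if self.role not in ROLES:
            raise PartError(f"unknown role {self.role!r} for part {self.part_id!r}")
        if not self.sequence or set(self.sequence) - DNA_ALPHABET:
            raise PartError(
                f"part {self.part_id!r}: sequence must be non-empty uppercase A/C/G/T"
            )
        for name, oh in (("overhang_5", self.overhang_5), ("overhang_3", self.overhang_3)):
            if len(oh) != 4 or set(oh) - DNA_ALPHABET:
                raise PartError(
                    f"part {self.part_id!r}: {name} must be exactly 4 nt of A/C/G/T, got {oh!r}"
                )
        if self.strength_class is not None and self.strength_class not in STRENGTH_CLASSES:
            raise PartError(
                f"part {self.part_id!r}: bad strength_class {self.strength_class!r}"
            )
        if not self.sequence.startswith(self.overhang_5):
            raise PartError(f"part {self.part_id!r}: sequence does not start with overhang_5")
        if not self.sequence.endswith(self.overhang_3):
            raise PartError(f"part {self.part_id!r}: sequence does not end with overhang_3")

    def __len__(self) -> int:
        return len(self.sequence)


class PartRegistry:
    """A validated collection of parts keyed by part_id."""

    def __init__(self, parts: Iterable[Part]):
        self._parts: dict[str, Part] = {}
        for part in parts:
            if part.part_id in self._parts:
                raise PartError(f"duplicate part_id {part.part_id!r}")
            self._parts[part.part_id] = part

    def __getitem__(self, part_id: str) -> Part:
        return self._parts[part_id]

    def __contains__(self, part_id: str) -> bool:
        return part_id in self._parts

    def __iter__(self):
        return iter(self._parts.values())

    def __len__(self) -> int:
        return len(self._parts)

    def by_role(self, role: str) -> list[Part]:
        """All parts filling one grammar slot, in registry order."""
        return [p for p in self if p.role == role]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self:
                fh.write(f">{p.part_id}\n{p.sequence}\n")


@dataclass(frozen=True)
class ConstructDesign:
    """An ordered, junction-validated assembly of one construct.

    ``genotype_key`` is the (promoter, signal peptide, CDS) triple that the
    read analysis recovers; ``display_mode`` distinguishes the anchored
    (surface display) cassette from the anchor-less (secretion) cassette.
    """

    parts: tuple[Part, ...]
    genotype_key: tuple[str, str, str]
    assembled_sequence: str
    display_mode: str

    def __len__(self) -> int:
        return len(self.assembled_sequence)

    @property
    def design_id(self) -> str:
        return "__".join(self.genotype_key)


def load_registry(parts_fasta: str | Path, manifest: str | Path) -> PartRegistry:
    """Load parts from a FASTA file plus a TSV manifest.

    The manifest must carry one row per FASTA record with columns
    ``part_id``, ``role``, ``overhang_5``, ``overhang_3`` and optionally
    ``strength_class``. Every FASTA record must have a manifest row.
    """
    man = pd.read_csv(manifest, sep="\t", dtype=str).fillna("")
    required = {"part_id", "role", "overhang_5", "overhang_3"}
    missing = required - set(man.columns)
    if missing:
        raise PartError(f"manifest missing columns: {sorted(missing)}")
    if man["part_id"].duplicated().any():
        dups = man.loc[man["part_id"].duplicated(), "part_id"].tolist()
        raise PartError(f"duplicate part_id in manifest: {dups}")
    rows = man.set_index("part_id")

    parts = []
    for rec in SeqIO.parse(str(parts_fasta), "fasta"):
        if rec.id not in rows.index:
            raise PartError(f"FASTA record {rec.id!r} has no manifest entry")
        row = rows.loc[rec.id]
        strength = row.get("strength_class", "") or None
        parts.append(
            Part(
                part_id=rec.id,
                role=row["role"],
                sequence=str(rec.seq).upper(),
                overhang_5=row["overhang_5"],
                overhang_3=row["overhang_3"],
                strength_class=strength if strength else None,
            )
        )
    return PartRegistry(parts)


def build_elp(n_units: int) -> str:
    """Build an elastin-like polypeptide of ``n_units`` 100-aa units.

    One unit is (VPGVG)5-(VPGAG)2-(VPGGG)3-(VPGVG)5-(VPGAG)2-(VPGGG)3,
    i.e. 20 pentapeptides = 100 residues.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    unit = "".join(block * count for block, count in _ELP_UNIT_BLOCKS)
    assert len(unit) == 100
    return unit * n_units


def elp_dna(n_units: int) -> str:
    """DNA encoding of an ELP, one fixed codon per amino acid (300 nt per unit)."""
    return "".join(_CODON[aa] for aa in build_elp(n_units))


def assemble(parts: Sequence[Part], mode: str = "display") -> ConstructDesign:
    """Assemble one construct from one part per slot, in grammar order.

    Junctions are validated (overhang_3 of part *i* must equal overhang_5 of
    part *i+1*) and the assembled sequence is scarless: each shared 4-nt
    junction appears once, so its length is sum(part lengths) - 4*(n-1).
    """
    if len(parts) != len(SLOT_ORDER):
        raise PartError(f"expected {len(SLOT_ORDER)} parts, got {len(parts)}")
    for slot, part in zip(SLOT_ORDER, parts):
        if part.role != slot:
            raise PartError(
                f"wrong slot order: expected role {slot!r}, got {part.role!r} ({part.part_id})"
            )
    if mode not in ("display", "secrete"):
        raise PartError(f"mode must be 'display' or 'secrete', got {mode!r}")

    for i in range(len(parts) - 1):
        left, right = parts[i], parts[i + 1]
        if left.overhang_3 != right.overhang_5:
            raise PartError(
                f"overhang mismatch at junction {i}: "
                f"{left.part_id} 3'={left.overhang_3!r} vs {right.part_id} 5'={right.overhang_5!r}"
            )

    seq = parts[0].sequence
    for part in parts[1:]:
        seq += part.sequence[4:]  # shared junction counted once

    return ConstructDesign(
        parts=tuple(parts),
        genotype_key=(parts[0].part_id, parts[1].part_id, parts[2].part_id),
        assembled_sequence=seq,
        display_mode=mode,
    )


def enumerate_design_space(
    promoters: Sequence[Part],
    sps: Sequence[Part],
    cds: Part,
    fusion_4a: Part | None = None,
    cassette_4b: Part | None = None,
    mode: str = "display",
) -> list[ConstructDesign]:
    """Enumerate the full promoter x signal-peptide design space for one CDS.

    Returns len(promoters) * len(sps) constructs with unique genotype keys.
    """
    if not promoters or not sps:
        raise PartError("promoter and signal-peptide lists must be non-empty")
    if fusion_4a is None or cassette_4b is None:
        raise PartError("fusion_4a and cassette_4b parts are required")
    designs = [
        assemble([prom, sp, cds, fusion_4a, cassette_4b], mode=mode)
        for prom in promoters
        for sp in sps
    ]
    keys = {d.genotype_key for d in designs}
    assert len(keys) == len(designs), "genotype keys must be unique"
    return designs


def designs_to_fasta(designs: Iterable[ConstructDesign], path: str | Path) -> None:
    """Export constructs as FASTA; the genotype key is the record id."""
    with open(path, "w") as fh:
        for d in designs:
            fh.write(f">{d.design_id}\n{d.assembled_sequence}\n")
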
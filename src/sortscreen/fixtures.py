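"""Synthetic stand-ins for the toolkit parts and pool barcodes.

The real promoter, signal-peptide and cassette sequences of the screened
libraries are not published, so every sequence here is generated from a fixed
seed. Only the properties the analysis depends on are preserved: the grammar
slots and strength classes, internally consistent 4-nt overhangs, part lengths
that put a full display amplicon at ~2.3-3.3 kb (so the 2 kb full-amplicon
filter behaves realistically), and 24-nt pool barcodes with pairwise edit
distance >= 8 so error-tolerant demultiplexing is testable.
"""

from __future__ import annotations

from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .parts import Part, PartRegistry, elp_dna

FIXTURE_SEED = 20_240_817

#: promoter ids and strength classes; strong = pYTK009-pYTK015 bin.
PROMOTERS: dict[str, str] = {
    **{f"pYTK{i:03d}": "strong" for i in (9, 10, 11, 12, 13, 14, 15)},
    **{f"pYTK{i:03d}": "medium" for i in (16, 18, 20, 21, 22, 23)},
    **{f"pYTK{i:03d}": "weak" for i in (17, 19, 24, 25, 26, 27, 28)},
}

SIGNAL_PEPTIDES = ("MF", "STA1", "SUC2", "AMY")

#: non-ELP coding sequences: beta-lactamase and alpha-galactosidase (Mel1)
CDS_LENGTHS = {"BLA": 861, "Mel1": 1413}

#: one forward barcode per ORF library (4 x 3 gates = 12 distinguishable pools)
ORF_LIBRARIES = ("ELP2", "ELP4", "BLA", "Mel1")

#: the three libraries pooled and sequenced in the default screen
SEQUENCED_LIBRARIES = ("ELP2", "ELP4", "BLA")

GATES = ("low", "medium", "high")

BARCODE_LEN = 24
MIN_BARCODE_DIST = 8


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _with_overhangs(body: str, oh5: str, oh3: str) -> str:
    return oh5 + body + oh3


def make_registry(seed: int = FIXTURE_SEED) -> PartRegistry:
    """Build the demo part registry: 20 promoters, 4 SPs, 3 CDSs, 4a, two 4b.

    Overhangs are arbitrary but consistent across junctions, matching the
    grammar promoter-(AACG)-sp-(TTCT)-cds-(GGAT)-4a-(CCGA)-4b. Promoter bodies
    are 450-700 nt so the shortest full display amplicon clears 2 kb.
    """
    rng = np.random.default_rng(seed)
    oh = {"start": "CACC", "p_sp": "AACG", "sp_cds": "TTCT", "cds_4a": "GGAT", "4a_4b": "CCGA", "end": "GCTT"}

    parts: list[Part] = []
    for pid, strength in PROMOTERS.items():
        body = _random_dna(rng, int(rng.integers(450, 701)) - 8)
        parts.append(
            Part(pid, "promoter", _with_overhangs(body, oh["start"], oh["p_sp"]),
                 oh["start"], oh["p_sp"], strength)
        )
    for sp in SIGNAL_PEPTIDES:
        body = _random_dna(rng, 150 - 8)
        parts.append(Part(sp, "sp_flag", _with_overhangs(body, oh["p_sp"], oh["sp_cds"]),
                          oh["p_sp"], oh["sp_cds"]))
    # ELP coding sequences are deterministic repeat DNA; BLA-like ORF is random.
    for name, n_units in (("ELP2", 2), ("ELP4", 4)):
        body = elp_dna(n_units)
        parts.append(Part(name, "cds", _with_overhangs(body, oh["sp_cds"], oh["cds_4a"]),
                          oh["sp_cds"], oh["cds_4a"]))
    for name, length in CDS_LENGTHS.items():
        body = _random_dna(rng, length - 8)
        parts.append(Part(name, "cds", _with_overhangs(body, oh["sp_cds"], oh["cds_4a"]),
                          oh["sp_cds"], oh["cds_4a"]))
    # 4a: cellulose-binding module, also the 3' orientation marker.
    cbm = _random_dna(rng, 350 - 8)
    parts.append(Part("CBM", "fusion_4a", _with_overhangs(cbm, oh["cds_4a"], oh["4a_4b"]),
                      oh["cds_4a"], oh["4a_4b"]))
    # 4b cassettes: display carries the anchor ORF, secrete does not.
    secrete_body = _random_dna(rng, 500 - 8)
    anchor = _random_dna(rng, 300)
    parts.append(Part("cassette_secrete", "cassette_4b",
                      _with_overhangs(secrete_body, oh["4a_4b"], oh["end"]),
                      oh["4a_4b"], oh["end"]))
    parts.append(Part("cassette_display", "cassette_4b",
                      _with_overhangs(secrete_body + anchor, oh["4a_4b"], oh["end"]),
                      oh["4a_4b"], oh["end"]))
    return PartRegistry(parts)


def make_barcodes(seed: int = FIXTURE_SEED) -> pd.DataFrame:
    """Generate pool barcodes: one forward per ORF library, one reverse per gate.

    24-nt sequences drawn by rejection sampling until every pair is at
    edit distance >= 8 (forward and reverse sets jointly).
    """
    rng = np.random.default_rng(seed + 1)
    chosen: list[str] = []
    while len(chosen) < len(ORF_LIBRARIES) + len(GATES):
        cand = _random_dna(rng, BARCODE_LEN)
        if all(
            edlib.align(cand, prev, mode="NW")["editDistance"] >= MIN_BARCODE_DIST
            for prev in chosen
        ):
            chosen.append(cand)
    rows = []
    for lib, seq in zip(ORF_LIBRARIES, chosen):
        rows.append({"barcode_id": f"fwd_{lib}", "role": "fwd", "pool": lib, "sequence": seq})
    for gate, seq in zip(GATES, chosen[len(ORF_LIBRARIES):]):
        rows.append({"barcode_id": f"rev_{gate}", "role": "rev", "pool": gate, "sequence": seq})
    return pd.DataFrame(rows)


def write_fixtures(out_dir: str | Path, seed: int = FIXTURE_SEED) -> dict[str, Path]:
    """Write the parts FASTA + manifest and the barcode manifest to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = make_registry(seed)
    fasta = out / "parts.fasta"
    manifest = out / "parts.tsv"
    registry.to_fasta(fasta)
    pd.DataFrame(
        [
            {
                "part_id": p.part_id,
                "role": p.role,
                "overhang_5": p.overhang_5,
                "overhang_3": p.overhang_3,
                "strength_class": p.strength_class or "",
            }
            for p in registry
        ]
    ).to_csv(manifest, sep="\t", index=False)
    barcodes = out / "barcodes.tsv"
    make_barcodes(seed).to_csv(barcodes, sep="\t", index=False)
    return {"parts_fasta": fasta, "parts_manifest": manifest, "barcodes": barcodes}
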
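"""Ground-truthed simulation of FACS sorting and nanopore amplicon sequencing.

The generative model mirrors the screening experiment: every genotype
(promoter, signal peptide, CDS) is assigned a mean log10 display fluorescence;
cells drawn from the library composition fluoresce Normal(mu_g, sigma) on the
log10 scale and are sorted into low / medium / high gates, with the band
between low and medium deliberately excluded. Each sorted pool is then PCR
amplified with a forward (ORF library) and reverse (gate) barcode and
sequenced as long amplicon reads with nanopore-like substitution/indel noise,
random strand, and optional CDS-truncated ("false-high") or chimeric
templates. Every read records its hidden truth for downstream benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parts import ConstructDesign

GATES = ("low", "medium", "high")

#: default mean log10 fluorescence by (promoter strength, signal peptide);
#: strong promoters with MF/STA1 dominate the high gate, weak promoters sit
#: near the 10^2 background, spanning the 10^2-10^5 instrument range.
DEFAULT_STRENGTH_SP_MU: dict[tuple[str, str], float] = {
    ("strong", "MF"): 4.8,
    ("strong", "STA1"): 4.4,
    ("strong", "SUC2"): 3.6,
    ("strong", "AMY"): 3.3,
    ("medium", "MF"): 3.9,
    ("medium", "STA1"): 3.6,
    ("medium", "SUC2"): 3.0,
    ("medium", "AMY"): 2.8,
    ("weak", "MF"): 3.0,
    ("weak", "STA1"): 2.8,
    ("weak", "SUC2"): 2.5,
    ("weak", "AMY"): 2.4,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FluorescenceModel:
    """Per-genotype mean log10 fluorescence plus a shared spread.

    ``mu`` maps genotype_key -> mean log10 fluorescence in [2, 5] (the
    instrument's printed 10^2-10^5 span); ``sigma`` is the shared log10
    standard deviation; ``background_mu`` is the non-displaying baseline.
    """

    mu: dict[tuple[str, str, str], float]
    sigma: float = 0.3
    background_mu: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        for key, value in self.mu.items():
            if not (2.0 <= value <= 5.0):
                raise ValueError(f"mu for {key} = {value} outside [2, 5]")


@dataclass(frozen=True)
class GateModel:
    """Sorting gates on the log10 fluorescence axis.

    low = (-inf, t_low); excluded = [t_low, t_mid); medium = [t_mid, t_high);
    high = [t_high, inf). Intervals are left-closed, so a cell exactly at a
    threshold falls in the higher bin; excluded cells are discarded.
    """

    t_low: float = 2.7
    t_mid: float = 3.2
    t_high: float = 4.2

    def __post_init__(self) -> None:
        if not (self.t_low < self.t_mid < self.t_high):
            raise ValueError("gate thresholds must satisfy t_low < t_mid < t_high")

    def gate_of(self, log_fluor: float) -> str | None:
        """Gate label for one cell, or None for the excluded band."""
        if log_fluor < self.t_low:
            return "low"
        if log_fluor < self.t_mid:
            return None
        if log_fluor < self.t_high:
            return "medium"
        return "high"


@dataclass(frozen=True)
class ErrorModel:
    """Per-base read error rates plus template-level artefact probabilities."""

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.03
    truncation_prob: float = 0.0
    chimera_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 0.2):
                raise ValueError(f"{name} must lie in [0, 0.2], got {rate}")
        for name in ("truncation_prob", "chimera_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")

    @property
    def noise_free(self) -> bool:
        return self.sub_rate == self.ins_rate == self.del_rate == 0.0


@dataclass
class ReadRecord:
    """One simulated read with its hidden truth."""

    read_id: str
    sequence: str
    quality: str
    genotype_key: tuple[str, str, str] | None = None
    gate: str | None = None
    orf_pool: str | None = None
    strand: str | None = None
    truncated: bool = False
    chimeric: bool = False


def assign_fluorescence(
    designs: Sequence[ConstructDesign],
    strength_sp_mu: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
    jitter_sd: float = 0.05,
    sigma: float = 0.3,
) -> FluorescenceModel:
    """Assign each genotype a mean log10 fluorescence from its promoter
    strength class and signal peptide, plus a small seeded genotype-level
    jitter so genotypes within a class remain distinguishable.
    """
    table = dict(DEFAULT_STRENGTH_SP_MU if strength_sp_mu is None else strength_sp_mu)
    rng = np.random.default_rng(seed)
    mu: dict[tuple[str, str, str], float] = {}
    for design in sorted(designs, key=lambda d: d.genotype_key):
        promoter = design.parts[0]
        if promoter.strength_class is None:
            raise ValueError(f"promoter {promoter.part_id} has no strength_class")
        key = (promoter.strength_class, design.genotype_key[1])
        if key not in table:
            raise ValueError(f"no fluorescence mapping for {key}")
        value = table[key] + rng.normal(0.0, jitter_sd)
        mu[design.genotype_key] = float(np.clip(value, 2.0, 5.0))
    return FluorescenceModel(mu=mu, sigma=sigma)


def sort_cells(
    model: FluorescenceModel,
    gates: GateModel,
    composition: Mapping[tuple[str, str, str], float],
    n_cells: int,
    seed: int = 0,
) -> dict[str, dict[tuple[str, str, str], int]]:
    """Sort ``n_cells`` from the library through the FACS gate model.

    Each cell picks a genotype from ``composition``, draws log10 fluorescence
    Normal(mu_g, sigma) and is binned; cells in the excluded band are dropped,
    so returned counts sum to <= n_cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    keys = sorted(composition)
    freqs = np.array([composition[k] for k in keys], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition frequencies sum to {freqs.sum()}, not 1")
    rng = np.random.default_rng(seed)
    genotype_idx = rng.choice(len(keys), size=n_cells, p=freqs)
    mus = np.array([model.mu[k] for k in keys])
    fluor = rng.normal(mus[genotype_idx], model.sigma)

    pools: dict[str, dict[tuple[str, str, str], int]] = {g: {} for g in GATES}
    for idx, x in zip(genotype_idx, fluor):
        gate = gates.gate_of(float(x))
        if gate is None:
            continue
        key = keys[idx]
        pools[gate][key] = pools[gate].get(key, 0) + 1
    return pools


def gate_probabilities(mu: float, sigma: float, gates: GateModel) -> dict[str, float]:
    """Closed-form Normal-CDF probability of each gate (and the excluded band)
    for a genotype with mean ``mu`` — the convergence target of sort_cells."""
    from scipy.stats import norm

    cdf = lambda t: norm.cdf(t, loc=mu, scale=sigma)
    return {
        "low": cdf(gates.t_low),
        "excluded": cdf(gates.t_mid) - cdf(gates.t_low),
        "medium": cdf(gates.t_high) - cdf(gates.t_mid),
        "high": 1.0 - cdf(gates.t_high),
    }


def _mutate(seq: str, errors: ErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion noise."""
    if errors.noise_free:
        return seq
    bases = "ACGT"
    out: list[str] = []
    for base in seq:
        r = rng.random()
        if r < errors.del_rate:
            continue
        if r < errors.del_rate + errors.sub_rate:
            sub = bases[int(rng.integers(4))]
            while sub == base:  # substitutions always change the base
                sub = bases[int(rng.integers(4))]
            out.append(sub)
        else:
            out.append(base)
        if rng.random() < errors.ins_rate:
            out.append(bases[int(rng.integers(4))])
    return "".join(out)


def simulate_reads(
    gate_pools: Mapping[str, Mapping[tuple[str, str, str], int]],
    designs: Sequence[ConstructDesign],
    barcodes: pd.DataFrame,
    errors: ErrorModel,
    reads_per_pool: int,
    seed: int = 0,
    orf_pool: str | None = None,
) -> list[ReadRecord]:
    """Emit barcoded amplicon reads for every gate pool of one ORF library.

    Each read is fwd_barcode + amplicon + rev_barcode where the amplicon is
    the assembled construct, with the CDS part excised (scarlessly, keeping
    one junction copy) for truncated templates. Reads are mutated per the
    error model and reverse-complemented with probability 0.5; genotypes are
    sampled proportionally to their sorted cell counts.
    """
    if reads_per_pool < 1:
        raise ValueError("reads_per_pool must be >= 1")
    by_key = {d.genotype_key: d for d in designs}
    fwd = barcodes[barcodes["role"] == "fwd"].set_index("pool")["sequence"]
    rev = barcodes[barcodes["role"] == "rev"].set_index("pool")["sequence"]
    if orf_pool is None:
        if len(fwd) != 1:
            raise ValueError("orf_pool must be given when several forward barcodes exist")
        orf_pool = str(fwd.index[0])
    if orf_pool not in fwd.index:
        raise ValueError(f"no forward barcode for ORF pool {orf_pool!r}")

    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    for gate in GATES:
        pool = gate_pools.get(gate, {})
        if not pool:
            continue
        if gate not in rev.index:
            raise ValueError(f"no reverse barcode for gate {gate!r}")
        keys = sorted(pool)
        counts = np.array([pool[k] for k in keys], dtype=float)
        probs = counts / counts.sum()
        picks = rng.choice(len(keys), size=reads_per_pool, p=probs)
        for i, pick in enumerate(picks):
            key = keys[pick]
            design = by_key[key]
            truncated = rng.random() < errors.truncation_prob
            amplicon = _amplicon_sequence(design, truncated)
            chimeric = rng.random() < errors.chimera_prob
            if chimeric:
                partner = by_key[keys[int(rng.integers(len(keys)))]]
                amplicon = amplicon + _amplicon_sequence(partner, False)
            template = fwd[orf_pool] + amplicon + rev.loc[gate]
            template = _mutate(template, errors, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = template if strand == "+" else revcomp(template)
            reads.append(
                ReadRecord(
                    read_id=f"{orf_pool}_{gate}_{i:06d}",
                    sequence=seq,
                    quality="I" * len(seq),
                    genotype_key=key,
                    gate=gate,
                    orf_pool=orf_pool,
                    strand=strand,
                    truncated=truncated,
                    chimeric=chimeric,
                )
            )
    return reads


def _amplicon_sequence(design: ConstructDesign, truncated: bool) -> str:
    """Assembled amplicon, optionally lacking the CDS part (length drops by
    len(CDS) - 4: the excised part's two junctions collapse into one)."""
    if not truncated:
        return design.assembled_sequence
    seq = design.parts[0].sequence
    for part in design.parts[1:]:
        if part.role == "cds":
            continue
        seq += part.sequence[4:]
    return seq


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def write_truth(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Truth table TSV: read_id, genotype_key, gate, strand, truncated, chimeric."""
    rows = [
        {
            "read_id": r.read_id,
            "genotype": "__".join(r.genotype_key) if r.genotype_key else "",
            "orf_pool": r.orf_pool or "",
            "gate": r.gate or "",
            "strand": r.strand or "",
            "truncated": r.truncated,
            "chimeric": r.chimeric,
        }
        for r in reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
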
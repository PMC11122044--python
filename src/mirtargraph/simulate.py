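"""Seeded generator of desk-scale plant-like miRNA/transcript datasets.

Plant miRNAs bind their targets through near-perfect reverse-complement
sites, so a recoverable association signal can be planted by embedding the
reverse complement of each miRNA into its target transcripts. The generator
emulates three features of real data:

* miRNA *families*: each family has a 21-nt core; members carry a few
  seeded point mutations of the core (plant family members typically differ
  at 1-3 nt).
* transcripts: i.i.d. background bases at configurable composition, with one
  or more non-overlapping reverse-complement sites of the assigned miRNA
  embedded at random positions; each site base is flipped with probability
  ``mutation_rate`` to emulate imperfect pairing.
* a truth table: exactly the planted (miRNA, target) pairs.

Everything is driven by one ``numpy`` Generator, so a fixed seed reproduces
the FASTA bytes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AssociationList,
    SequenceRecord,
    write_associations,
    write_fasta,
)

__all__ = ["SimConfig", "SimOutput", "simulate", "export", "reverse_complement"]

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults give 2 families x 3 members = 6 miRNAs and 60 targets of 500 nt
    carrying one planted site each — orders of magnitude below real genomes
    but large enough for the k-mer signal to dominate sampling noise.
    """

    n_families: int = 2
    mirnas_per_family: int = 3
    n_targets: int = 60
    sites_per_target: int = 1
    mirna_length: int = 21
    target_length: int = 500
    background_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mutation_rate: float = 0.02
    member_mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "mirnas_per_family", "n_targets", "mirna_length", "target_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sites_per_target < 0:
            raise ValueError("sites_per_target must be >= 0")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if not (0.0 <= self.member_mutation_rate <= 1.0):
            raise ValueError("member_mutation_rate must be in [0, 1]")
        p = np.asarray(self.background_base_probs, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("background_base_probs must be 4 probabilities summing to 1")
        if self.sites_per_target * self.mirna_length > self.target_length:
            raise ValueError(
                f"{self.sites_per_target} sites of {self.mirna_length} nt do not fit "
                f"in a {self.target_length}-nt target"
            )


@dataclass
class SimOutput:
    mirna_records: list[SequenceRecord]
    target_records: list[SequenceRecord]
    truth: AssociationList
    config: SimConfig = field(repr=False, default=None)


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(_BASES, size=length, p=list(probs)))


def _mutate(rng: np.random.Generator, seq: str, rate: float, force_change: bool) -> str:
    """Flip each base with probability ``rate``; ``force_change`` guarantees a
    flipped base differs from the original (used so rate=1 means every base
    differs)."""
    out = []
    for b in seq:
        if rate > 0 and rng.random() < rate:
            if force_change:
                choices = [c for c in "ACGU" if c != b]
                out.append(choices[rng.integers(len(choices))])
            else:
                out.append(str(rng.choice(_BASES)))
        else:
            out.append(b)
    return "".join(out)


def simulate(config: SimConfig | None = None) -> SimOutput:
    """Generate miRNA families, transcripts with planted sites, and truth pairs.

    Each target is assigned ``sites_per_target`` distinct miRNAs (uniformly,
    cycling so every miRNA gets targets); for each assignment one mutated
    reverse-complement site is embedded at a random non-overlapping position.
    With ``sites_per_target = 0`` targets are pure background and the truth
    table is empty (the null control).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    probs = config.background_base_probs

    mirnas: list[SequenceRecord] = []
    for f in range(config.n_families):
        core = _random_seq(rng, config.mirna_length, probs)
        for m in range(config.mirnas_per_family):
            seq = _mutate(rng, core, config.member_mutation_rate, force_change=True)
            mirnas.append(
                SequenceRecord(
                    id=f"miR-f{f + 1}-{m + 1}", sequence=seq, role="miRNA"
                )
            )

    n_mirna = len(mirnas)
    targets: list[SequenceRecord] = []
    pairs: list[tuple[str, str]] = []
    for t in range(config.n_targets):
        seq = list(_random_seq(rng, config.target_length, probs))
        if config.sites_per_target > 0:
            # cycle through miRNAs so coverage is even, then top up randomly
            first = t % n_mirna
            extra = rng.choice(
                [i for i in range(n_mirna) if i != first],
                size=min(config.sites_per_target - 1, n_mirna - 1),
                replace=False,
            ) if config.sites_per_target > 1 else []
            assigned = [first, *map(int, extra)]
            positions = _nonoverlapping_positions(
                rng, config.target_length, config.mirna_length, len(assigned)
            )
            for mi, pos in zip(assigned, positions):
                site = reverse_complement(mirnas[mi].sequence)
                site = _mutate(rng, site, config.mutation_rate, force_change=True)
                seq[pos : pos + config.mirna_length] = list(site)
                pairs.append((mirnas[mi].id, f"tgt-{t + 1}"))
        targets.append(
            SequenceRecord(id=f"tgt-{t + 1}", sequence="".join(seq), role="target")
        )
    return SimOutput(
        mirna_records=mirnas,
        target_records=targets,
        truth=AssociationList(pairs=pairs),
        config=config,
    )


def _nonoverlapping_positions(
    rng: np.random.Generator, total: int, width: int, count: int
) -> list[int]:
    """Random start positions for ``count`` non-overlapping windows."""
    for _ in range(1000):
        starts = sorted(rng.integers(0, total - width + 1, size=count).tolist())
        if all(b - a >= width for a, b in zip(starts, starts[1:])):
            return starts
    raise ValueError(f"could not place {count} non-overlapping sites of {width} nt in {total} nt")


def export(sim: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write mirnas.fasta, targets.fasta and pairs.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": directory / "mirnas.fasta",
        "targets": directory / "targets.fasta",
        "pairs": directory / "pairs.tsv",
    }
    write_fasta(sim.mirna_records, paths["mirnas"])
    write_fasta(sim.target_records, paths["targets"])
    write_associations(sim.truth, paths["pairs"])
    return paths
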
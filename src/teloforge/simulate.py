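"""Synthetic genomes with planted chromosome-end events and full ground truth.

The generator emulates the structures the chromosome-end analysis is built to
detect: a multi-chromosome reference carrying two subtelomeric duplication
families (defaults 9 kb and 8 kb, 16 copies each, one interstitial
"ancestral" copy per family), trio haplotypes with terminal
extension-by-duplication, terminal deletion and terminal tandem-expansion
events, noisy optical-map contigs, error-bearing long reads, and a
duplication-pair table consistent with the planted families.  Every planted
structure is recorded in a :class:`SimTruth` ledger against which the
downstream calling stages are scored.

Background sequence is i.i.d. uniform A/C/G/T: the analysis depends only on
label and duplication structure, not composition.  The default enzyme motif
GCTCTTC (an Nt.BspQI-like 7-mer) gives a label every ~8.2 kb on random
sequence, the spacing regime of real optical maps.  All subtelomeric copies
are placed in terminus-distal orientation (q-arm copies forward, p-arm copies
reverse-complemented), the orientation convention of real subtelomeric
duplications.

Determinism: one master seed; per-stage substreams derived from the stage
name, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .label_io import LabelMap, digest, merge_labels

__all__ = [
    "NoiseParams",
    "EndEvent",
    "Placement",
    "SimConfig",
    "SimTruth",
    "MemberRecord",
    "SimRead",
    "ConfigurationError",
    "simulate_reference",
    "simulate_trio",
    "apply_end_event",
    "simulate_contig_maps",
    "simulate_long_reads",
    "simulate_terminal_read",
    "emit_segdup_table",
    "segdup_table_from_truth",
    "default_config",
    "write_fasta",
    "read_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """Invalid simulation configuration (bounds, overlaps, conflicts)."""


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``divergence``."""
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < divergence)[0]
    for i in hit:
        alts = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([alts[rng.integers(3)]])
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class NoiseParams:
    """Contig-level optical-map noise.

    Defaults follow the published assembler error parameters: fixed sizing SD
    sf 0.20 kb, relative sizing error sr 0.01, false positives 0.6 per 100 kb,
    false-negative rate 0.06, and resolution 2.9 label units (~500 bp each).
    """

    sizing_sd_fixed: float = 200.0   # bp
    sizing_sd_rel: float = 0.01      # fraction of interval length
    fp_rate: float = 0.6             # false labels per 100 kb
    fn_rate: float = 0.06            # fraction of true labels missed
    resolution_bp: float = 1450.0    # minimum resolvable inter-label distance

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ConfigurationError(f"NoiseParams.{name} must be >= 0")
        if not 0 <= self.fn_rate <= 1:
            raise ConfigurationError("fn_rate must be in [0, 1]")


@dataclass
class EndEvent:
    """A planted chromosome-end event on one haplotype.

    kind: 'extension_by_duplication' (append the donor arm's terminal
    ``length`` bp in terminus-distal orientation), 'terminal_deletion'
    (remove the distal ``length`` bp), or 'tandem_expansion' (replace the
    terminal ``length``-bp unit with ``copies`` concatenated copies).
    """

    kind: str
    target: tuple[str, str]           # (chrom, arm)
    length: int
    donor: tuple[str, str] | None = None
    copies: int | None = None
    carrier: str = "f1"

    def __post_init__(self) -> None:
        if self.kind not in (
            "extension_by_duplication", "terminal_deletion", "tandem_expansion"
        ):
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.length < 0:
            raise ConfigurationError("event length must be >= 0")
        if self.kind == "extension_by_duplication" and self.donor is None:
            raise ConfigurationError("extension_by_duplication requires a donor")
        if self.kind != "extension_by_duplication" and self.donor is not None:
            raise ConfigurationError("donor is only valid for extension_by_duplication")
        if self.kind == "tandem_expansion" and (self.copies is None or self.copies < 1):
            raise ConfigurationError("tandem_expansion requires copies >= 1")
        self.target = tuple(self.target)
        if self.donor is not None:
            self.donor = tuple(self.donor)

    @property
    def net_gain(self) -> int:
        """Signed change in chromosome length."""
        if self.kind == "extension_by_duplication":
            return self.length
        if self.kind == "terminal_deletion":
            return -self.length
        return (self.copies - 1) * self.length


@dataclass
class Placement:
    """One duplication-family copy: family index, chromosome, arm
    ('p'/'q'/'i' for interstitial) and offset.  For arms the offset is the
    distance from the terminus to the copy's terminus-proximal edge; for
    interstitial copies it is the forward start coordinate."""

    family: int
    chrom: str
    arm: str
    offset: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q", "i"):
            raise ConfigurationError(f"arm must be 'p', 'q' or 'i', got {self.arm!r}")


@dataclass
class MemberRecord:
    """A planted duplication-family copy in reference coordinates."""

    family: int
    chrom: str
    start: int
    end: int
    strand: str
    arm: str
    divergence: float


@dataclass
class SimRead:
    """A simulated long read with its source coordinates."""

    id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class SimConfig:
    n_chromosomes: int = 5
    chrom_length: int = 5_000_000
    enzyme_motif: str = "GCTCTTC"
    dup_unit_lengths: tuple[int, ...] = (9000, 8000)
    placements: list[Placement] = field(default_factory=list)
    divergence_schedule: list[float] = field(default_factory=list)
    event_list: list[EndEvent] = field(default_factory=list)
    contig_noise: NoiseParams = field(default_factory=NoiseParams)
    read_length_mean: int = 30_000
    read_length_min: int = 1_000
    read_error_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        max_event = max((abs(e.net_gain) for e in self.event_list), default=0)
        max_event = max(max_event, max((e.length for e in self.event_list), default=0))
        if self.chrom_length <= 2 * max_event:
            raise ConfigurationError("chrom_length must exceed 2x the largest event")
        if not 0 <= self.read_error_rate <= 1:
            raise ConfigurationError("read_error_rate must be in [0, 1]")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x

        return plain(asdict(self))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["placements"] = [Placement(**p) for p in d.get("placements", [])]
        d["event_list"] = [
            EndEvent(**{**e, "target": tuple(e["target"]),
                        "donor": tuple(e["donor"]) if e.get("donor") else None})
            for e in d.get("event_list", [])
        ]
        d["contig_noise"] = NoiseParams(**d.get("contig_noise", {}))
        d["dup_unit_lengths"] = tuple(d.get("dup_unit_lengths", (9000, 8000)))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_placements(
    n_chromosomes: int = 5, chrom_length: int = 5_000_000
) -> tuple[list[Placement], list[float]]:
    """Default copy layout: per family, 15 subtelomeric copies across the
    2*n arms plus one interstitial ancestral copy; pairwise subtelomeric
    divergence in the sub-percent range and a several-percent-diverged
    ancestor, mirroring the ranges seen between real family copies."""
    arms = [(f"chr{i + 1}", a) for i in range(n_chromosomes) for a in ("p", "q")]
    placements: list[Placement] = []
    divergence: list[float] = []
    # per-copy substitution fractions; pairwise divergence is ~ the sum of two
    subtel_div = [0.0001, 0.0002, 0.0004, 0.0006, 0.0008, 0.0010, 0.0013,
                  0.0016, 0.0019, 0.0022, 0.0025, 0.0028, 0.0031, 0.0035, 0.0039]
    # Offsets vary per arm so no two subtelomeres share an identical label
    # constellation: real subtelomeric blocks differ per arm in spacing and
    # content, and identical layouts would make entire arms paralogous to
    # each other at the label level.
    n_arms = len(arms)
    slots: dict[int, list[tuple[str, str, int]]] = {0: [], 1: []}
    for k, (chrom, arm) in enumerate(arms):
        o0 = 12_000 + 6_000 * k
        o1 = o0 + 9_000 + 4_000 + 2_300 * k
        slots[0].append((chrom, arm, o0))
        slots[1].append((chrom, arm, o1))
    for k, (chrom, arm) in enumerate(arms[: max(0, 15 - n_arms)]):
        o0b = 12_000 + 6_000 * k + 9_000 + 4_000 + 2_300 * k + 8_000 + 11_000 + 3_900 * k
        o1b = o0b + 9_000 + 15_000 + 2_900 * k
        slots[0].append((chrom, arm, o0b))
        slots[1].append((chrom, arm, o1b))
    for fam in (0, 1):
        for k, (chrom, arm, off) in enumerate(slots[fam][:15]):
            placements.append(Placement(fam, chrom, arm, off))
            divergence.append(subtel_div[k])
        # interstitial ancestral copy, markedly diverged
        mid = chrom_length // 2 + fam * 100_000
        placements.append(Placement(fam, f"chr{fam + 1}", "i", mid))
        divergence.append(0.02)
    return placements, divergence


def default_config(**overrides) -> SimConfig:
    n = overrides.pop("n_chromosomes", 5)
    L = overrides.pop("chrom_length", 5_000_000)
    placements, schedule = default_placements(n, L)
    cfg = SimConfig(
        n_chromosomes=n,
        chrom_length=L,
        placements=overrides.pop("placements", placements),
        divergence_schedule=overrides.pop("divergence_schedule", schedule),
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# truth ledger


@dataclass
class SimTruth:
    """Planted-event ledger: what downstream stages must recover."""

    events: list[EndEvent] = field(default_factory=list)
    members: list[MemberRecord] = field(default_factory=list)
    inheritance: dict[str, str] = field(default_factory=dict)  # child hap -> parent hap
    family_units: list[str] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def events_for(self, hap: str, chrom: str, arm: str) -> list[EndEvent]:
        """Events effective on one haplotype terminus, including inherited."""
        carriers = {hap}
        parent = self.inheritance.get(hap)
        if parent:
            carriers.add(parent)
        return [
            e for e in self.events
            if e.carrier in carriers and e.target == (chrom, arm)
        ]

    def expected_status(
        self, hap: str, chrom: str, arm: str, threshold_bp: float
    ) -> str:
        ext = sum(max(e.net_gain, 0) for e in self.events_for(hap, chrom, arm))
        miss = sum(-min(e.net_gain, 0) for e in self.events_for(hap, chrom, arm))
        has_ext = ext > threshold_bp
        has_miss = miss > threshold_bp
        if has_ext and has_miss:
            return "extension_and_missing"
        if has_ext:
            return "extension"
        if has_miss:
            return "missing"
        return "reference"

    def to_json(self, path: str | Path) -> None:
        d = {
            "events": [asdict(e) for e in self.events],
            "members": [asdict(m) for m in self.members],
            "inheritance": self.inheritance,
            "family_units": self.family_units,
            "chrom_lengths": self.chrom_lengths,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            events=[
                EndEvent(**{**e, "target": tuple(e["target"]),
                            "donor": tuple(e["donor"]) if e.get("donor") else None})
                for e in d["events"]
            ],
            members=[MemberRecord(**m) for m in d["members"]],
            inheritance=d["inheritance"],
            family_units=d["family_units"],
            chrom_lengths={k: int(v) for k, v in d["chrom_lengths"].items()},
        )


# ---------------------------------------------------------------------------
# reference and events


def _placement_interval(p: Placement, unit_len: int, chrom_len: int) -> tuple[int, int, str]:
    if p.arm == "q":
        start = chrom_len - p.offset - unit_len
        return start, start + unit_len, "+"
    if p.arm == "p":
        return p.offset, p.offset + unit_len, "-"
    return p.offset, p.offset + unit_len, "+"


def simulate_reference(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate the reference genome with planted duplication families.

    Each placement receives a copy of its family unit, independently mutated
    at its scheduled substitution fraction; subtelomeric copies are oriented
    terminus-distally.  Truth records every member interval.
    """
    rng = _rng(config.seed, "reference")
    units = [
        _random_seq(_rng(config.seed, f"unit{f}"), u)
        for f, u in enumerate(config.dup_unit_lengths)
    ]
    genome = {name: _random_seq(rng, config.chrom_length) for name in config.chrom_names()}
    truth = SimTruth(
        family_units=list(units),
        chrom_lengths={n: config.chrom_length for n in config.chrom_names()},
        events=list(config.event_list),
    )

    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in genome}
    mut_rng = _rng(config.seed, "placement-divergence")
    for k, p in enumerate(config.placements):
        if p.chrom not in genome:
            raise ConfigurationError(f"placement on unknown chromosome {p.chrom!r}")
        if p.family >= len(units):
            raise ConfigurationError(f"placement family {p.family} out of range")
        u = len(units[p.family])
        start, end, strand = _placement_interval(p, u, config.chrom_length)
        if start < 0 or end > config.chrom_length:
            raise ConfigurationError(
                f"placement {p} exceeds chromosome bounds [0, {config.chrom_length})"
            )
        for s0, e0 in occupied[p.chrom]:
            if start < e0 and s0 < end:
                raise ConfigurationError(f"placement {p} overlaps another placement")
        occupied[p.chrom].append((start, end))
        d = (
            config.divergence_schedule[k % len(config.divergence_schedule)]
            if config.divergence_schedule
            else 0.0
        )
        copy = _mutate(units[p.family], d, mut_rng)
        if strand == "-":
            copy = reverse_complement(copy)
        seq = genome[p.chrom]
        genome[p.chrom] = seq[:start] + copy + seq[end:]
        truth.members.append(
            MemberRecord(p.family, p.chrom, start, end, strand, p.arm, d)
        )
    return genome, truth


def _donor_segment(reference: Mapping[str, str], donor: tuple[str, str], length: int) -> str:
    """The donor arm's terminal ``length`` bp, oriented so it can be appended
    to a q-arm terminus (terminus-distal orientation)."""
    chrom, arm = donor
    seq = reference[chrom]
    if length > len(seq):
        raise ConfigurationError("event length exceeds donor chromosome")
    return seq[-length:] if arm == "q" else reverse_complement(seq[:length])


def apply_end_event(
    haplotype: str, event: EndEvent, reference: Mapping[str, str]
) -> str:
    """Apply one chromosome-end event to a haplotype sequence.

    p-arm events are handled by mirroring: the sequence is
    reverse-complemented into terminus-distal orientation, the q-arm logic
    applied, then mirrored back (one code path; matches the terminus-distal
    orientation convention of subtelomeric duplications).
    """
    _, arm = event.target
    if arm == "p":
        mirrored = reverse_complement(haplotype)
        mirrored = _apply_q(mirrored, event, reference)
        return reverse_complement(mirrored)
    return _apply_q(haplotype, event, reference)


def _apply_q(seq: str, event: EndEvent, reference: Mapping[str, str]) -> str:
    L = event.length
    if L == 0:
        return seq
    if L >= len(seq):
        raise ConfigurationError("event length exceeds chromosome length")
    if event.kind == "extension_by_duplication":
        return seq + _donor_segment(reference, event.donor, L)
    if event.kind == "terminal_deletion":
        return seq[:-L]
    unit = seq[-L:]
    return seq[:-L] + unit * event.copies


def simulate_trio(
    reference: Mapping[str, str],
    event_list: Sequence[EndEvent],
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[dict, dict, dict, SimTruth]:
    """Build father/mother/child diploid genomes from the reference.

    Parental haplotypes (f1, f2, m1, m2) start as reference copies; events
    are applied to their carrier haplotype, then the child receives one
    haplotype from each parent (c1 paternal, c2 maternal), recorded in truth.
    Events carried by c1/c2 are applied after transmission.
    """
    truth = truth or SimTruth(chrom_lengths={c: len(s) for c, s in reference.items()})
    truth.events = list(event_list)
    haps: dict[str, dict[str, str]] = {
        h: dict(reference) for h in ("f1", "f2", "m1", "m2")
    }
    seen: set[tuple[str, str, str]] = set()
    for e in event_list:
        key = (e.carrier, *e.target)
        if key in seen:
            raise ConfigurationError(f"conflicting events on terminus {key}")
        seen.add(key)
        if e.carrier not in ("f1", "f2", "m1", "m2", "c1", "c2"):
            raise ConfigurationError(f"unknown carrier {e.carrier!r}")
        chrom = e.target[0]
        if chrom not in reference:
            raise ConfigurationError(f"event targets unknown chromosome {chrom!r}")
        if e.carrier in haps:
            haps[e.carrier][chrom] = apply_end_event(haps[e.carrier][chrom], e, reference)

    rng = _rng(seed, "transmission")
    pf = ("f1", "f2")[rng.integers(2)]
    pm = ("m1", "m2")[rng.integers(2)]
    child = {"c1": dict(haps[pf]), "c2": dict(haps[pm])}
    truth.inheritance = {"c1": pf, "c2": pm}
    for e in event_list:
        if e.carrier in ("c1", "c2"):
            chrom = e.target[0]
            child[e.carrier][chrom] = apply_end_event(child[e.carrier][chrom], e, reference)
    father = {"f1": haps["f1"], "f2": haps["f2"]}
    mother = {"m1": haps["m1"], "m2": haps["m2"]}
    return father, mother, child, truth


# ---------------------------------------------------------------------------
# optical-map contigs


def simulate_contig_maps(
    genome: Mapping[str, str],
    enzyme_motif: str,
    noise: NoiseParams,
    seed: int,
    id_suffix: str = "",
) -> list[LabelMap]:
    """One noisy contig label map per sequence.

    True label positions are perturbed through their inter-label intervals
    with Gaussian error of SD sqrt(sd_fixed^2 + (sd_rel * interval)^2), true
    labels are dropped independently at fn_rate, false labels arrive as a
    Poisson process at fp_rate per 100 kb, and labels closer than
    resolution_bp are merged to their centroid.
    """
    rng = _rng(seed, "contigs")
    maps: list[LabelMap] = []
    for name, seq in genome.items():
        true = digest(seq, enzyme_motif)
        bounds = np.concatenate([[0.0], true, [float(len(seq))]])
        iv = np.diff(bounds)
        if noise.sizing_sd_fixed > 0 or noise.sizing_sd_rel > 0:
            sd = np.sqrt(noise.sizing_sd_fixed**2 + (noise.sizing_sd_rel * iv) ** 2)
            iv = np.maximum(iv + rng.normal(0.0, 1.0, iv.size) * sd, 1.0)
        new_bounds = np.concatenate([[0.0], np.cumsum(iv)])
        length = float(new_bounds[-1])
        labels = new_bounds[1:-1]
        if noise.fn_rate > 0 and labels.size:
            labels = labels[rng.random(labels.size) >= noise.fn_rate]
        n_fp = rng.poisson(noise.fp_rate * length / 1e5) if noise.fp_rate > 0 else 0
        if n_fp:
            labels = np.concatenate([labels, rng.uniform(0.0, length, n_fp)])
        labels = np.unique(labels)
        if noise.resolution_bp > 0 and labels.size:
            labels = merge_labels(labels, noise.resolution_bp)
        labels = labels[(labels >= 0) & (labels < length)]
        maps.append(
            LabelMap(f"{name}{id_suffix}", length, labels, meta={"source": name})
        )
    return maps


# ---------------------------------------------------------------------------
# long reads


def _apply_read_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitutions / insertions / deletions at ``error_rate`` per base
    (60/20/20 mix)."""
    if error_rate <= 0:
        return seq
    out = []
    errs = rng.random(len(seq)) < error_rate
    kinds = rng.random(len(seq))
    ins = rng.choice(_BASES, size=max(1, int(errs.sum())))
    subs = rng.integers(1, 4, size=max(1, int(errs.sum())))
    k = 0
    for i, ch in enumerate(seq):
        if not errs[i]:
            out.append(ch)
            continue
        u = kinds[i]
        if u < 0.6:  # substitution to a different base
            out.append("ACGT"[("ACGT".index(ch) + subs[k]) % 4])
        elif u < 0.8:  # insertion before the base
            out.append(ins[k].decode())
            out.append(ch)
        # else deletion: emit nothing
        k += 1
    return "".join(out)


def simulate_long_reads(
    genome: Mapping[str, str],
    n_reads: int,
    length_mean: int,
    length_min: int,
    error_rate: float,
    seed: int,
) -> list[SimRead]:
    """Reads sampled uniformly over the genome with strand flips and errors."""
    rng = _rng(seed, "reads")
    names = list(genome)
    lens = np.array([len(genome[n]) for n in names], dtype=float)
    if length_mean >= lens.min():
        raise ConfigurationError("mean read length must be below chromosome length")
    probs = lens / lens.sum()
    reads = []
    for i in range(n_reads):
        chrom = names[rng.choice(len(names), p=probs)]
        L = int(length_min + rng.exponential(max(length_mean - length_min, 1)))
        start = int(rng.integers(0, max(len(genome[chrom]) - length_min, 1)))
        end = min(start + L, len(genome[chrom]))
        raw = genome[chrom][start:end]
        strand = "+-"[rng.integers(2)]
        if strand == "-":
            raw = reverse_complement(raw)
        reads.append(
            SimRead(f"read{i}", _apply_read_errors(raw, error_rate, rng),
                    chrom, start, end, strand)
        )
    return reads


def simulate_terminal_read(
    genome: Mapping[str, str],
    chrom: str,
    arm: str,
    length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> SimRead:
    """A read anchored at a terminus: the chromosome tip is the read's last
    base (q arms read forward, p arms reverse-complemented)."""
    seq = genome[chrom]
    length = min(length, len(seq))
    if arm == "q":
        raw, start, end, strand = seq[-length:], len(seq) - length, len(seq), "+"
    else:
        raw, start, end, strand = reverse_complement(seq[:length]), 0, length, "-"
    rng = _rng(seed, f"terminal-{chrom}{arm}")
    return SimRead(
        f"terminal_{chrom}{arm}", _apply_read_errors(raw, error_rate, rng),
        chrom, start, end, strand,
    )


# ---------------------------------------------------------------------------
# duplication-pair table


def emit_segdup_table(
    members: Sequence[MemberRecord],
    identities: Mapping[tuple[int, int], float] | None = None,
    both_orders: bool = False,
) -> pd.DataFrame:
    """BED-like duplication-pair table: one record per unordered pair of
    same-family members (n members -> n*(n-1)/2 records), with an identity
    column.

    ``both_orders=True`` lists each pair in both orientations (2 records per
    pair), the convention of the real whole-genome segmental-duplication
    database; that convention is what makes a 16-copy family reach the
    paper-scale base-pair copy-number depth.
    """
    rows = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if a.family != b.family:
                continue
            if identities is not None:
                ident = identities[(i, j)] if (i, j) in identities else identities[(j, i)]
            else:
                ident = max(0.0, 1.0 - (a.divergence + b.divergence))
            rec = (a.chrom, a.start, a.end, b.chrom, b.start, b.end, round(ident, 6))
            rows.append(rec)
            if both_orders:
                rows.append((b.chrom, b.start, b.end, a.chrom, a.start, a.end, rec[6]))
    return pd.DataFrame(
        rows,
        columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "identity"],
    )


def segdup_table_from_truth(
    truth: SimTruth,
    genome: Mapping[str, str] | None = None,
    both_orders: bool = False,
) -> pd.DataFrame:
    """Duplication-pair table for the planted families; with a genome the
    identity column is measured by direct base comparison of the oriented
    member sequences rather than taken from the divergence schedule."""
    identities = None
    if genome is not None:
        def oriented(m: MemberRecord) -> str:
            s = genome[m.chrom][m.start:m.end]
            return reverse_complement(s) if m.strand == "-" else s

        identities = {}
        for i in range(len(truth.members)):
            for j in range(i + 1, len(truth.members)):
                a, b = truth.members[i], truth.members[j]
                if a.family != b.family:
                    continue
                sa, sb = oriented(a), oriented(b)
                same = sum(x == y for x, y in zip(sa, sb))
                identities[(i, j)] = same / max(len(sa), 1)
    return emit_segdup_table(truth.members, identities, both_orders=both_orders)


# ---------------------------------------------------------------------------
# FASTA I/O


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
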
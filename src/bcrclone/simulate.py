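"""Synthetic Ig heavy-chain repertoire generator with known ground truth.

The generator emulates the statistical structure of a sorted-cell BCR-seq
experiment on autoimmune mice: four populations (germinal-centre B cells and
three memory subsets MBC1-3), two isotypes with IgM dominant, three dominant
V families (VH1, VH5, VH14), heavy-tailed clonal expansions some of which
span several populations, and population-dependent somatic-hypermutation
loads (MBC2 lowest).

Model
-----
* V(D)J recombination: founder = V[0:end-trimV] + N1 + D[trimD5:end-trimD3]
  + N2 + J[trimJ:], trims uniform on [0, trim_max], N-insert lengths uniform
  on [0, n_insert_max] with bases uniform over ACGT; resampled until the
  junction is in frame and free of stop codons.
* Clonal lineages grow by sequential uniform attachment (Yule-type): member
  i attaches to a uniformly chosen earlier member (or the founder). Each
  edge carries a Poisson number of point substitutions placed on distinct
  V-encoded positions, with the mean set by the child's population; the
  non-V part of the junction mutates at a separate (lower) per-branch rate.
  No indels are simulated, so every member stays length-aligned to its
  germline.
* Truth tables record the clone partition, the lineage forest (parent
  pointers) and the per-edge V mutation count, which by construction equals
  the V-region hamming distance between child and parent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .io import (
    GermlineSegment,
    ISOTYPES,
    NUCLEOTIDES,
    POPULATIONS,
    REGIONS,
    translate_nt,
)

# Fixed IMGT-style V layout used for all synthetic V segments (nt, half-open).
V_REGION_LAYOUT = {
    "FR1": (0, 78),
    "CDR1": (78, 102),
    "FR2": (102, 153),
    "CDR2": (153, 177),
    "FR3": (177, 291),
}
V_LENGTH = 291

#: Offset of the conserved J-Trp codon (TGG) inside every synthetic J segment.
J_TRP_OFFSET = 6
J_TAIL_CODONS = 13

_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOP_CODONS
)


@dataclass
class SimulationConfig:
    """Study-shaped defaults for the synthetic repertoire.

    Mutation rates are expected substitutions per branch per 100 V
    nucleotides; population weights follow the per-sequence proportions of
    the sorted samples (MBC3 largest, MBC2 smallest); isotype switch
    probabilities make IgM dominant with MBC1 carrying the most switched
    cells (25%); 7% of clones are seeded across >=2 populations.
    """

    seed: int = 0
    n_clones: int = 800
    clone_size_distribution: dict = field(
        default_factory=lambda: {"alpha": 2.0, "max_size": 100}
    )
    populations: dict = field(
        default_factory=lambda: {"GC": 0.25, "MBC1": 0.20, "MBC2": 0.10, "MBC3": 0.45}
    )
    per_population_mutation_rate: dict = field(
        default_factory=lambda: {"GC": 2.4, "MBC1": 2.2, "MBC2": 1.0, "MBC3": 2.0}
    )
    isotype_switch_probability: dict = field(
        default_factory=lambda: {"GC": 0.20, "MBC1": 0.25, "MBC2": 0.10, "MBC3": 0.10}
    )
    shared_clone_fraction: float = 0.07
    shared_rate_multiplier: float = 1.0
    junction_mutation_rate: float = 0.1
    trim_max: int = 4
    n_insert_max: int = 6
    n_v_per_family: int = 2
    v_family_weights: dict = field(
        default_factory=lambda: {"VH1": 0.40, "VH5": 0.35, "VH14": 0.25}
    )

    def validate(self) -> None:
        for name, weights in (("populations", self.populations),
                              ("v_family_weights", self.v_family_weights)):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} weights must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ConfigurationError(f"{name} weights must be >= 0")
        if any(r < 0 for r in self.per_population_mutation_rate.values()):
            raise ConfigurationError("mutation rates must be >= 0")
        for p in self.isotype_switch_probability.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("switch probabilities must be in [0, 1]")
        if not 0.0 <= self.shared_clone_fraction <= 1.0:
            raise ConfigurationError("shared_clone_fraction must be in [0, 1]")
        if self.junction_mutation_rate < 0 or self.shared_rate_multiplier < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.n_clones < 1 or self.n_v_per_family < 1:
            raise ConfigurationError("counts must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TruthRecord:
    """Ground-truth bookkeeping for one simulated cell."""

    sequence_id: str
    true_clone_id: str
    true_parent_id: str
    true_mutation_count: int


@dataclass
class Founder:
    """A naive (unmutated) V(D)J rearrangement in founder coordinates."""

    sequence: str
    v_call: str
    d_call: str
    j_call: str
    v_germline_end: int      # V reference nt retained (alignment prefix length)
    j_germline_start: int    # 1-based start within the J reference
    junction_start: int      # 0-based, inclusive (conserved Cys codon start)
    junction_end: int        # 0-based, exclusive (end of conserved Trp codon)

    @property
    def junction(self) -> str:
        return self.sequence[self.junction_start:self.junction_end]

    @property
    def cdr3_start(self) -> int:
        """1-based inclusive CDR3 start (junction minus the Cys codon)."""
        return self.junction_start + 3 + 1

    @property
    def cdr3_end(self) -> int:
        """1-based inclusive CDR3 end (junction minus the Trp codon)."""
        return self.junction_end - 3


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n codons drawn from the 61 non-stop codons."""
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def build_germline_set(n_per_family: int, seed: int) -> dict[str, GermlineSegment]:
    """Generate a reference set: V segments for VH1/VH5/VH14, plus D and J.

    Every V segment is 291 nt with the fixed IMGT-style FR/CDR layout and
    ends in the conserved Cys codon (TGT); J segments carry the conserved
    Trp codon (TGG) at a fixed offset. Deterministic for a fixed seed.
    """
    if n_per_family < 1:
        raise ConfigurationError("n_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    segments: dict[str, GermlineSegment] = {}
    for family_number in (1, 5, 14):
        for i in range(1, n_per_family + 1):
            seq = _random_codons(rng, V_LENGTH // 3 - 1) + "TGT"
            name = f"IGHV{family_number}-{i}*01"
            segments[name] = GermlineSegment(
                name=name, family=f"VH{family_number}", kind="V",
                sequence=seq, region_map=dict(V_REGION_LAYOUT),
            )
    n_dj = max(2, n_per_family)
    for i in range(1, n_dj + 1):
        length = int(rng.integers(12, 19))
        name = f"IGHD1-{i}*01"
        segments[name] = GermlineSegment(
            name=name, family="DH1", kind="D",
            sequence="".join(rng.choice(_BASES, length)),
        )
    for i in range(1, n_dj + 1):
        head = "".join(rng.choice(np.array(list("ACT")), J_TRP_OFFSET))  # no stray G-runs
        seq = head + "TGG" + _random_codons(rng, J_TAIL_CODONS)
        name = f"IGHJ{i}*01"
        segments[name] = GermlineSegment(name=name, family=f"JH{i}", kind="J", sequence=seq)
    return segments


def simulate_rearrangement(
    germlines: dict[str, GermlineSegment],
    rng: np.random.Generator,
    trim_max: int = 4,
    n_insert_max: int = 6,
    v_name: str | None = None,
    max_attempts: int = 200,
) -> Founder:
    """Draw one naive V(D)J rearrangement.

    Trims are uniform on [0, trim_max] (J trimming capped so the conserved
    Trp survives), N-insert lengths uniform on [0, n_insert_max]. Junction
    frame and absence of stop codons are guaranteed by resampling; failing
    ``max_attempts`` raises :class:`SimulationError`.
    """
    by_name = lambda s: s.name
    vs = sorted((s for s in germlines.values() if s.kind == "V"), key=by_name)
    ds = sorted((s for s in germlines.values() if s.kind == "D"), key=by_name)
    js = sorted((s for s in germlines.values() if s.kind == "J"), key=by_name)
    if not (vs and ds and js):
        raise ConfigurationError("germline set must contain at least one V, D and J")
    v = germlines[v_name] if v_name else vs[rng.integers(len(vs))]

    for _ in range(max_attempts):
        # D/J are re-drawn per attempt: a rare D/J pairing can make a
        # stop-free in-frame junction unreachable
        d = ds[rng.integers(len(ds))]
        j = js[rng.integers(len(js))]
        trim_v = int(rng.integers(0, trim_max + 1))
        trim_d5 = int(rng.integers(0, trim_max + 1))
        trim_d3 = int(rng.integers(0, trim_max + 1))
        trim_j = int(rng.integers(0, min(trim_max, J_TRP_OFFSET) + 1))
        if len(d.sequence) - trim_d5 - trim_d3 < 1:
            continue
        n1 = "".join(rng.choice(_BASES, int(rng.integers(0, n_insert_max + 1))))
        n2 = "".join(rng.choice(_BASES, int(rng.integers(0, n_insert_max + 1))))
        v_part = v.sequence[: len(v.sequence) - trim_v]
        d_part = d.sequence[trim_d5 : len(d.sequence) - trim_d3]
        j_part = j.sequence[trim_j:]
        seq = v_part + n1 + d_part + n2 + j_part

        junction_start = 3 * (len(v_part) // 3) - 3
        j_start = len(v_part) + len(n1) + len(d_part) + len(n2)
        junction_end = j_start + (J_TRP_OFFSET - trim_j) + 3
        if junction_start < 0 or (junction_end - junction_start) % 3 != 0:
            continue
        if junction_end - junction_start < 9:
            continue
        junction = seq[junction_start:junction_end]
        if "*" in translate_nt(junction):
            continue
        return Founder(
            sequence=seq, v_call=v.name, d_call=d.name, j_call=j.name,
            v_germline_end=len(v_part), j_germline_start=trim_j + 1,
            junction_start=junction_start, junction_end=junction_end,
        )
    raise SimulationError("could not produce an in-frame junction")


def _mutate(sequence: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute each listed position with a uniformly chosen different base."""
    chars = list(sequence)
    for pos in positions:
        current = chars[pos]
        choices = [b for b in "ACGT" if b != current]
        chars[pos] = choices[rng.integers(3)]
    return "".join(chars)


def simulate_lineage(
    founder: Founder,
    clone_size: int,
    population_assignment: list[str],
    mutation_model: dict[str, float],
    rng: np.random.Generator,
    clone_id: str = "C0",
    junction_rate: float = 0.0,
    isotype_switch_probability: dict[str, float] | None = None,
) -> tuple[list[dict], list[TruthRecord]]:
    """Grow one clonal lineage from a founder by sequential attachment.

    ``mutation_model`` maps population -> expected V mutations per branch
    (absolute count); the edge rate is set by the child's population. The
    non-V junction part mutates at ``junction_rate`` per branch. Returns the
    member records (dicts with AIRR fields) and their truth records.
    """
    if clone_size < 1:
        raise ConfigurationError("clone_size must be >= 1")
    if len(population_assignment) != clone_size:
        raise ConfigurationError("population_assignment must have one label per member")
    switch = isotype_switch_probability or {}

    v_positions = np.arange(founder.v_germline_end)
    junction_positions = np.arange(founder.v_germline_end, founder.junction_end)
    founder_id = f"{clone_id}-founder"

    sequences = [founder.sequence]       # index 0 = founder (virtual)
    ids = [founder_id]
    records: list[dict] = []
    truth: list[TruthRecord] = []
    for i in range(clone_size):
        parent_idx = int(rng.integers(0, len(sequences)))
        population = population_assignment[i]
        rate = mutation_model.get(population, 0.0)
        n_v = int(rng.poisson(rate)) if rate > 0 else 0
        n_v = min(n_v, len(v_positions))
        muts = rng.choice(v_positions, size=n_v, replace=False) if n_v else np.empty(0, int)
        seq = _mutate(sequences[parent_idx], muts, rng)
        if junction_rate > 0 and len(junction_positions):
            n_j = min(int(rng.poisson(junction_rate)), len(junction_positions))
            if n_j:
                jmuts = rng.choice(junction_positions, size=n_j, replace=False)
                seq = _mutate(seq, jmuts, rng)
        isotype = "IgG" if rng.random() < switch.get(population, 0.0) else "IgM"
        seq_id = f"{clone_id}-{i + 1:04d}"
        junction = seq[founder.junction_start:founder.junction_end]
        records.append({
            "sequence_id": seq_id,
            "population": population,
            "isotype": isotype,
            "v_call": founder.v_call,
            "j_call": founder.j_call,
            "sequence_alignment": seq,
            "germline_alignment": "",
            "junction": junction,
            "junction_aa": translate_nt(junction),
            "duplicate_count": 1,
            "cdr3_start": founder.cdr3_start,
            "cdr3_end": founder.cdr3_end,
            "v_germline_end": founder.v_germline_end,
            "j_germline_start": founder.j_germline_start,
            "clone_id": "",
        })
        truth.append(TruthRecord(
            sequence_id=seq_id, true_clone_id=clone_id,
            true_parent_id=ids[parent_idx], true_mutation_count=n_v,
        ))
        sequences.append(seq)
        ids.append(seq_id)
    return records, truth


def _draw_clone_sizes(rng: np.random.Generator, n: int, params: dict) -> np.ndarray:
    """Heavy-tailed clone sizes: truncated discrete power law P(k) ~ k^-alpha.

    ``{"fixed": k}`` gives constant clone sizes (used for calibration runs
    where size must be decoupled from sharing).
    """
    if "fixed" in params:
        return np.full(n, int(params["fixed"]))
    alpha = float(params.get("alpha", 2.0))
    max_size = int(params.get("max_size", 100))
    ks = np.arange(1, max_size + 1)
    pmf = ks.astype(float) ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def _draw_populations(rng, size: int, shared: bool, labels, weights) -> list[str]:
    """Population labels per member; shared clones must span >=2 populations."""
    if not shared:
        return [labels[rng.choice(len(labels), p=weights)]] * size
    for _ in range(1000):
        draw = rng.choice(len(labels), size=size, p=weights)
        if len(set(draw)) >= 2:
            return [labels[i] for i in draw]
    raise SimulationError("could not draw a multi-population clone")


def simulate_repertoire(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, GermlineSegment]]:
    """Simulate a full repertoire.

    Returns ``(airr, truth_records, truth_clones, germlines)`` where ``airr``
    is an AIRR-shaped DataFrame (one row per cell, deterministic for a fixed
    config), ``truth_records`` carries the lineage forest and per-edge
    mutation counts and ``truth_clones`` the clone-level ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    germlines = build_germline_set(config.n_v_per_family, config.seed)

    pop_labels = sorted(config.populations)
    pop_weights = np.array([config.populations[p] for p in pop_labels], float)
    pop_weights /= pop_weights.sum()
    fam_labels = sorted(config.v_family_weights)
    fam_weights = np.array([config.v_family_weights[f] for f in fam_labels], float)
    fam_weights /= fam_weights.sum()
    v_by_family = {
        fam: sorted(s.name for s in germlines.values() if s.kind == "V" and s.family == fam)
        for fam in fam_labels
    }

    sizes = _draw_clone_sizes(rng, config.n_clones, config.clone_size_distribution)
    eligible = np.flatnonzero(sizes >= 2)
    n_shared = min(round(config.shared_clone_fraction * config.n_clones), len(eligible))
    shared_idx = set(rng.choice(eligible, size=n_shared, replace=False)) if n_shared else set()

    all_records: list[dict] = []
    all_truth: list[TruthRecord] = []
    clone_rows: list[dict] = []
    for c in range(config.n_clones):
        clone_id = f"C{c + 1:05d}"
        size = int(sizes[c])
        shared = c in shared_idx
        fam = fam_labels[rng.choice(len(fam_labels), p=fam_weights)]
        v_name = v_by_family[fam][rng.integers(len(v_by_family[fam]))]
        founder = simulate_rearrangement(
            germlines, rng, trim_max=config.trim_max,
            n_insert_max=config.n_insert_max, v_name=v_name,
        )
        populations = _draw_populations(rng, size, shared, pop_labels, pop_weights)
        multiplier = config.shared_rate_multiplier if shared else 1.0
        model = {
            p: r * founder.v_germline_end / 100.0 * multiplier
            for p, r in config.per_population_mutation_rate.items()
        }
        records, truth = simulate_lineage(
            founder, size, populations, model, rng,
            clone_id=clone_id, junction_rate=config.junction_mutation_rate,
            isotype_switch_probability=config.isotype_switch_probability,
        )
        all_records.extend(records)
        all_truth.extend(truth)
        clone_rows.append({
            "true_clone_id": clone_id, "clone_size": size,
            "designated_shared": shared, "v_call": founder.v_call,
            "j_call": founder.j_call, "founder_junction": founder.junction,
            "founder_junction_aa": translate_nt(founder.junction),
        })

    airr = pd.DataFrame(all_records)
    truth_records = pd.DataFrame([dataclasses.asdict(t) for t in all_truth])
    truth_clones = pd.DataFrame(clone_rows)
    return airr, truth_records, truth_clones, germlines
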
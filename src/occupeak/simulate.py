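"""Synthetic genomes and ChIP-seq read libraries with planted truth.

The generator emulates the statistical structure the analysis assumes: a
circular bacterial genome, planted direct/inverted repeat pairs, planted
occupancy sites with per-site IP enrichment factors, an origin-proximal
copy-number gradient (exponentially growing cells carry more origin-proximal
DNA), fixed-length single-end reads sampled from sonication fragments, and
exact reads so anchoring is stringency-limited rather than error-limited.

Model
-----
Fragments have uniform lengths on ``fragment_range`` (the study's sonication
size windows were 150-300 and 300-500 bp).  A fragment's start probability
is proportional to the copy-number gradient at its start; in the IP library
it is additionally multiplied by the site's enrichment factor when the
fragment overlaps a planted site, so the expected enrichment ratio at a
site center approaches the factor (with shoulders decaying over roughly one
fragment length on either side).  A read of ``read_length``
bases is emitted from the 5' end of a uniformly chosen fragment strand:
top-strand reads start at the fragment start, bottom-strand reads are the
reverse complement of the fragment's last ``read_length`` bases.  Qualities
are constant Q40 unless ``quality_degradation`` sets a per-base probability
of a low-quality (Q2-Q19) base call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import Genome, reverse_complement
from .intervals import IntervalSet
from .read_prep import Read, ReadLibrary


@dataclass
class PlantedRepeat:
    type: str  # direct | inverted
    i: int
    j: int
    position: int


@dataclass
class PlantedSite:
    start: int
    end: int
    factor: float


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset (deterministic given seed)."""

    genome_length: int = 50_000
    gc_fraction: float = 0.508  # E. coli-like base composition
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    #: (origin position, maximal relative copy number >= 1, decay span bp)
    gradient: tuple[int, float, int] | None = None
    read_length: int = 50
    n_control: int = 100_000
    n_ip: int = 100_000
    fragment_range: tuple[int, int] = (150, 300)
    quality_degradation: float = 0.0
    circular: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.read_length > self.fragment_range[0]:
            raise ValueError("read_length must not exceed the minimum fragment length")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome length")
        if self.n_control < 1 or self.n_ip < 1:
            raise ValueError("read counts must be >= 1")
        for site in self.planted_sites:
            if site.factor < 1:
                raise ValueError("enrichment factors must be >= 1")
            if not (0 <= site.start % self.genome_length < self.genome_length):
                raise ValueError("site outside genome")
            if site.end <= site.start:
                raise ValueError("empty site interval")
        if self.gradient is not None and self.gradient[1] < 1:
            raise ValueError("copy-number maximum must be >= 1")
        # planted repeat footprints must not contradict each other
        spans = [
            (r.position % self.genome_length,
             r.position % self.genome_length + 2 * r.i + r.j)
            for r in self.planted_repeats
        ]
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"planted repeats overlap at [{s2}, {min(e1, e2)}): "
                    "conflicting sequence constraints"
                )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class TruthSet:
    """Planted coordinates plus the expected relative coverage profile."""

    sites: list[PlantedSite]
    repeats: list[PlantedRepeat]
    expected_coverage: np.ndarray  # relative per-position copy number

    def site_intervals(self, genome_length: int) -> IntervalSet:
        pairs = []
        for s in self.sites:
            a, b = s.start % genome_length, s.start % genome_length + (s.end - s.start)
            if b <= genome_length:
                pairs.append((a, b))
            else:
                pairs.extend([(a, genome_length), (0, b - genome_length)])
        return IntervalSet(pairs, genome_length=genome_length, label="planted-sites")

    def sites_bed(self, path: str | Path, genome_id: str, genome_length: int) -> None:
        self.site_intervals(genome_length).to_bed(path, name="planted")

    def factors_tsv(self) -> str:
        lines = ["start\tend\tfactor"]
        for s in self.sites:
            lines.append(f"{s.start}\t{s.end}\t{s.factor}")
        return "\n".join(lines) + "\n"


def _gradient_profile(spec: SyntheticSpec) -> np.ndarray:
    """Relative copy number per position: linear decay from the origin."""
    g = spec.genome_length
    if spec.gradient is None:
        return np.ones(g)
    origin, peak, span = spec.gradient
    pos = np.arange(g)
    d = np.abs(pos - origin % g)
    if spec.circular:
        d = np.minimum(d, g - d)
    frac = np.minimum(d / max(span, 1), 1.0)
    return peak - (peak - 1.0) * frac


def make_genome(spec: SyntheticSpec) -> tuple[Genome, TruthSet]:
    """Random genome with planted repeat pairs; returns genome plus truth."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                       size=spec.genome_length, p=probs)
    seq = bytearray(bases.tobytes())
    g = spec.genome_length
    for rep in spec.planted_repeats:
        p = rep.position % g
        arm1 = bytes(seq[(p + k) % g] for k in range(rep.i))
        arm2 = (
            arm1
            if rep.type == "direct"
            else reverse_complement(arm1.decode()).encode()
        )
        for k, b in enumerate(arm2):
            seq[(p + rep.i + rep.j + k) % g] = b
    genome = Genome(id=f"synthetic_{spec.seed}", sequence=seq.decode(),
                    circular=spec.circular)
    truth = TruthSet(
        sites=list(spec.planted_sites),
        repeats=list(spec.planted_repeats),
        expected_coverage=_gradient_profile(spec),
    )
    return genome, truth


def _site_factor_profile(spec: SyntheticSpec) -> np.ndarray:
    g = spec.genome_length
    f = np.ones(g)
    for site in spec.planted_sites:
        for pos in range(site.start, site.end):
            f[pos % g] = max(f[pos % g], site.factor)
    return f


def sample_fragments(
    genome: Genome,
    spec: SyntheticSpec,
    n_frag: int,
    enriched: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample sonication fragments as (starts, lengths).

    Lengths are uniform on ``fragment_range``; the start probability is
    proportional to the copy-number gradient at the start, multiplied (IP
    only) by the site factor when the fragment overlaps a planted site, so
    the expected enrichment ratio at a site center approaches the factor.
    """
    from scipy.ndimage import maximum_filter1d

    g = spec.genome_length
    grad = _gradient_profile(spec)
    factor = _site_factor_profile(spec) if enriched else np.ones(g)
    fmin, fmax = spec.fragment_range
    lengths = rng.integers(fmin, fmax + 1, size=n_frag)
    starts = np.empty(n_frag, dtype=np.int64)
    # the overlap test depends on the fragment length, so sample per
    # distinct length
    for ln in np.unique(lengths):
        mask = lengths == ln
        if enriched:
            # factor of the strongest site the fragment [p, p+ln) touches
            f_ln = maximum_filter1d(
                factor, size=int(ln), origin=-(int(ln) // 2),
                mode="wrap" if genome.circular else "constant", cval=1.0,
            )
            w = grad * f_ln
        else:
            w = grad.copy()
        if not genome.circular:  # fragment must fit inside a linear genome
            w[g - int(ln) + 1 :] = 0
        cdf = np.cumsum(w)
        u = rng.random(int(mask.sum())) * cdf[-1]
        starts[mask] = np.searchsorted(cdf, u, side="right")
    return starts, lengths


def _sample_reads(
    genome: Genome,
    spec: SyntheticSpec,
    n_reads: int,
    enriched: bool,
    rng: np.random.Generator,
    prefix: str,
) -> ReadLibrary:
    g = spec.genome_length
    fmin, fmax = spec.fragment_range
    starts, lengths = sample_fragments(genome, spec, n_reads, enriched, rng)
    top = rng.random(n_reads) < 0.5
    L = spec.read_length
    # vectorized read emission: 5' end of a uniformly chosen fragment strand
    code = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    ext = np.concatenate([code, code[: max(fmax, L)]])
    pos5 = np.where(top, starts, starts + lengths - L).astype(np.int32)
    rows = ext[pos5[:, None] + np.arange(L, dtype=np.int32)]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    bottom = ~top
    rows[bottom] = comp[rows[bottom]][:, ::-1]
    seqs = [row.tobytes().decode() for row in rows]
    degrade = spec.quality_degradation
    reads: list[Read] = []
    if degrade > 0:
        for idx, s in enumerate(seqs):
            qual = np.full(L, 40, dtype=int)
            low = rng.random(L) < degrade
            qual[low] = rng.integers(2, 20, size=int(low.sum()))
            reads.append(Read(f"{prefix}_{idx:07d}", s, qual.tolist()))
    else:
        q40 = [40] * L  # shared constant-quality list
        reads = [Read(f"{prefix}_{idx:07d}", s, q40) for idx, s in enumerate(seqs)]
    return ReadLibrary(reads, label="ip" if enriched else "control")


def simulate_reads(
    genome: Genome, truth: TruthSet, spec: SyntheticSpec
) -> tuple[ReadLibrary, ReadLibrary]:
    """Control and IP libraries for a genome produced by :func:`make_genome`."""
    spec.validate()
    ctrl = _sample_reads(
        genome, spec, spec.n_control, enriched=False,
        rng=np.random.default_rng([spec.seed, 1]), prefix="ctrl",
    )
    ip = _sample_reads(
        genome, spec, spec.n_ip, enriched=True,
        rng=np.random.default_rng([spec.seed, 2]), prefix="ip",
    )
    return ctrl, ip
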
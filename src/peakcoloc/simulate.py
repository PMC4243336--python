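"""Synthetic paired-cistrome generator with controlled co-location structure.

Region lengths are log-normal: given a target (mean, median) the parameters
follow in closed form as mu = ln(median), sigma = sqrt(2 ln(mean / median))
(valid whenever mean > median, as in both emulated peak sets).  Three
scenarios are supported:

* ``null`` — query regions placed independently and uniformly;
* ``colocated`` — a fraction f of query regions centred on a randomly chosen
  reference region plus Normal(0, offset_sd) jitter;
* ``proximal`` — a fraction f of query regions starting just downstream of a
  reference region's end, at an Exponential(gap_mean) gap: nearby but
  (by construction) not overlapping their anchor.

Per-query truth labels ("tied" vs "independent") are part of the contract so
downstream tests never re-infer ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .intervals import GenomeLayout, GenomicInterval, IntervalSet

MIN_LENGTH = 50

# printed size summaries the length models emulate
PR_LIKE_MEAN, PR_LIKE_MEDIAN = 1508.0, 1336.0
ER_LIKE_MEAN, ER_LIKE_MEDIAN = 601.0, 529.0

SCENARIOS = ("null", "colocated", "proximal")

TIED, INDEPENDENT = "tied", "independent"


def lognormal_params(mean: float, median: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and median."""
    if median <= 0 or mean <= median:
        raise ValueError("need mean > median > 0 for a log-normal fit")
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return mu, sigma


def _default_layout() -> GenomeLayout:
    return GenomeLayout({f"chr{i + 1}": 20_000_000 for i in range(5)})


@dataclass
class LengthModel:
    mu: float
    sigma: float

    @classmethod
    def from_mean_median(cls, mean: float, median: float) -> "LengthModel":
        return cls(*lognormal_params(mean, median))

    def draw(self, n: int, rng: np.random.Generator, max_length: int) -> np.ndarray:
        """Truncated draw: resample anything outside [MIN_LENGTH, max_length]."""
        if max_length < MIN_LENGTH:
            raise ValueError("truncation bound below minimum region length")
        out = np.rint(rng.lognormal(self.mu, self.sigma, size=n)).astype(np.int64)
        bad = (out < MIN_LENGTH) | (out > max_length)
        guard = 0
        while bad.any():
            out[bad] = np.rint(
                rng.lognormal(self.mu, self.sigma, size=int(bad.sum()))
            ).astype(np.int64)
            bad = (out < MIN_LENGTH) | (out > max_length)
            guard += 1
            if guard > 1000:
                raise ValueError("length model cannot satisfy the truncation bounds")
        return out


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic paired-cistrome draw."""

    n_reference: int = 2_000
    n_query: int = 1_800
    ref_length_model: LengthModel = field(
        default_factory=lambda: LengthModel.from_mean_median(PR_LIKE_MEAN, PR_LIKE_MEDIAN)
    )
    query_length_model: LengthModel = field(
        default_factory=lambda: LengthModel.from_mean_median(ER_LIKE_MEAN, ER_LIKE_MEDIAN)
    )
    scenario: str = "null"
    coloc_fraction: float = 0.0
    offset_sd: float = 150.0
    gap_mean: float = 500.0
    seed: Optional[int] = None
    chromosome_lengths: dict = field(
        default_factory=lambda: {f"chr{i + 1}": 20_000_000 for i in range(5)}
    )

    def __post_init__(self):
        if self.n_reference <= 0 or self.n_query <= 0:
            raise ValueError("region counts must be positive")
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.offset_sd < 0 or self.gap_mean < 0:
            raise ValueError("offset_sd and gap_mean must be non-negative")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chromosome_lengths)

    @property
    def max_region_length(self) -> int:
        return min(self.chromosome_lengths.values()) // 100

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("ref_length_model", "query_length_model"):
            if key in d and isinstance(d[key], dict):
                d[key] = LengthModel(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_configs() -> dict[str, ScenarioConfig]:
    """Named presets: the two emulated length models plus a scaled-down pair."""
    return {
        "pr_like": ScenarioConfig(
            n_reference=2_000,
            n_query=2_000,
            ref_length_model=LengthModel.from_mean_median(PR_LIKE_MEAN, PR_LIKE_MEDIAN),
            query_length_model=LengthModel.from_mean_median(PR_LIKE_MEAN, PR_LIKE_MEDIAN),
            scenario="null",
        ),
        "er_like": ScenarioConfig(
            n_reference=2_000,
            n_query=2_000,
            ref_length_model=LengthModel.from_mean_median(ER_LIKE_MEAN, ER_LIKE_MEDIAN),
            query_length_model=LengthModel.from_mean_median(ER_LIKE_MEAN, ER_LIKE_MEDIAN),
            scenario="null",
        ),
        "paper_mimic": ScenarioConfig(
            n_reference=2_000,
            n_query=1_800,
            ref_length_model=LengthModel.from_mean_median(PR_LIKE_MEAN, PR_LIKE_MEDIAN),
            query_length_model=LengthModel.from_mean_median(ER_LIKE_MEAN, ER_LIKE_MEDIAN),
            scenario="colocated",
            coloc_fraction=0.25,
            offset_sd=150.0,
        ),
    }


def _allocate_counts(
    n: int, layout: GenomeLayout, rng: np.random.Generator
) -> dict[str, int]:
    chroms = layout.chromosomes
    lengths = np.array([layout.length_of(c) for c in chroms], dtype=float)
    counts = rng.multinomial(n, lengths / lengths.sum())
    return dict(zip(chroms, counts.tolist()))


def _clamp_starts(starts: np.ndarray, lengths: np.ndarray, clen: int) -> np.ndarray:
    return np.clip(starts, 0, clen - lengths)


def simulate_pair(
    config: ScenarioConfig,
) -> tuple[IntervalSet, IntervalSet, dict[str, str]]:
    """Draw (reference, query, truth) for one scenario.

    Truth maps query region names to "tied" (generated relative to a
    reference anchor) or "independent" (uniform placement).  Deterministic
    given ``config.seed``.
    """
    layout = config.layout
    rng = np.random.default_rng(config.seed)
    max_len = config.max_region_length
    if max_len < MIN_LENGTH:
        raise ValueError("chromosomes too short for the length truncation bound")

    # reference: uniform placement, counts proportional to chromosome length
    ref_counts = _allocate_counts(config.n_reference, layout, rng)
    ref_ivs: list[GenomicInterval] = []
    for chrom in layout.chromosomes:
        n_c = ref_counts[chrom]
        if n_c == 0:
            continue
        clen = layout.length_of(chrom)
        lens = config.ref_length_model.draw(n_c, rng, max_len)
        starts = rng.integers(0, clen - lens + 1)
        ref_ivs.extend(
            GenomicInterval(chrom, int(s), int(s + L))
            for s, L in zip(starts, lens)
        )
    reference = IntervalSet(ref_ivs, layout)

    n_tied = (
        int(math.floor(config.coloc_fraction * config.n_query))
        if config.scenario != "null"
        else 0
    )
    n_free = config.n_query - n_tied
    query_ivs: list[GenomicInterval] = []
    truth: dict[str, str] = {}
    width = len(str(config.n_query))

    # tied queries: anchored to uniformly chosen reference regions
    if n_tied:
        anchors = rng.choice(len(ref_ivs), size=n_tied, replace=n_tied > len(ref_ivs))
        lens = config.query_length_model.draw(n_tied, rng, max_len)
        if config.scenario == "colocated":
            jitter = np.rint(rng.normal(0.0, config.offset_sd, size=n_tied)).astype(
                np.int64
            )
        else:  # proximal
            gaps = np.floor(rng.exponential(config.gap_mean, size=n_tied)).astype(
                np.int64
            )
        for i in range(n_tied):
            anchor = ref_ivs[int(anchors[i])]
            L = int(lens[i])
            clen = layout.length_of(anchor.chrom)
            if config.scenario == "colocated":
                center = anchor.midpoint + int(jitter[i])
                start = center - L // 2
            else:
                start = anchor.end + int(gaps[i])
            start = int(np.clip(start, 0, clen - L))
            name = f"q{i:0{width}d}"
            query_ivs.append(GenomicInterval(anchor.chrom, start, start + L, name=name))
            truth[name] = TIED

    # independent queries: uniform placement like the reference
    free_counts = _allocate_counts(n_free, layout, rng) if n_free else {}
    j = n_tied
    for chrom in layout.chromosomes:
        n_c = free_counts.get(chrom, 0)
        if n_c == 0:
            continue
        clen = layout.length_of(chrom)
        lens = config.query_length_model.draw(n_c, rng, max_len)
        starts = rng.integers(0, clen - lens + 1)
        for s, L in zip(starts, lens):
            name = f"q{j:0{width}d}"
            query_ivs.append(GenomicInterval(chrom, int(s), int(s + L), name=name))
            truth[name] = INDEPENDENT
            j += 1
    query = IntervalSet(query_ivs, layout)
    return reference, query, truth


def write_truth(truth: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tlabel\n")
        for name in sorted(truth):
            fh.write(f"{name}\t{truth[name]}\n")
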
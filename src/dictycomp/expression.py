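"""Stage-resolved expression profiles and inter-species divergence calls.

Read counts are normalized per sample (raw / total reads x 2 x average
read length), rescaled to percent-of-maximum so profile shapes are
comparable across species and library sizes, and compared with a mean
absolute percent difference.  A gene counts as differentially
regulated only when one phylogenetic group's profile clearly differs
from the rest, and the divergence pattern is mapped onto the
dictyostelid phylogeny (single species, group 4 vs groups 1-3, or
branch I vs branch II).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import BRANCH_I, BRANCH_II, GROUP4

#: Canonical stage order (re-exported from the simulator's definition).
STAGES = (
    "growth",
    "early_aggregation",
    "late_aggregation",
    "tipped_mound",
    "slug",
    "early_culmination",
    "fruiting_body",
)

DEFAULT_THETA = 0.25

#: Editable default mapping of a 0-24 h (2-hourly) time course onto the
#: seven canonical stages.
DEFAULT_STAGE_MAP_24H = {
    0: "growth",
    2: "early_aggregation", 4: "early_aggregation",
    6: "late_aggregation", 8: "late_aggregation",
    10: "tipped_mound", 12: "tipped_mound",
    14: "slug", 16: "slug",
    18: "early_culmination", 20: "early_culmination",
    22: "fruiting_body", 24: "fruiting_body",
}

PATTERNS = ("conserved", "one_species", "group4_vs_123", "branchI_vs_II", "other")


@dataclass
class ExpressionSeries:
    """One gene's staged expression in one species."""

    gene: str
    species: str
    stages: tuple = STAGES
    raw: list = field(default_factory=list)
    normalized: list = field(default_factory=list)
    percent_of_max: list = field(default_factory=list)
    silent: bool = False


@dataclass(frozen=True)
class CellTypeRatio:
    gene: str
    species: str
    prespore_pct: float
    prestalk_pct: float
    undefined: bool = False


@dataclass(frozen=True)
class DivergenceResult:
    gene: str
    flags: tuple  # tuple of (species, bool)
    pattern: str
    theta: float

    @property
    def divergent_species(self):
        return tuple(sp for sp, f in self.flags if f)


def normalize_counts(raw: float, total_reads: float, avg_read_length: float) -> float:
    """Per-sample normalization: raw / total_reads x 2 x avg_read_length."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if avg_read_length <= 0:
        raise ValueError("avg_read_length must be > 0")
    return raw / total_reads * 2.0 * avg_read_length


def percent_of_max(values) -> tuple[list[float], bool]:
    """Rescale a series to percent of its maximum.

    Returns the profile and a silent flag; an all-zero series stays all
    zero and is flagged silent.
    """
    values = list(values)
    if len(values) < 2:
        raise ValueError("need at least 2 stages")
    peak = max(values)
    if peak <= 0:
        return [0.0] * len(values), True
    return [100.0 * v / peak for v in values], False


def build_series(gene, species, raw, total_reads, avg_read_length,
                 stages=STAGES) -> ExpressionSeries:
    """Assemble an ExpressionSeries from per-stage raw counts and sample sizes."""
    if not (len(raw) == len(total_reads) == len(avg_read_length) == len(stages)):
        raise ValueError("stage-wise inputs differ in length")
    norm = [normalize_counts(r, t, l)
            for r, t, l in zip(raw, total_reads, avg_read_length)]
    pct, silent = percent_of_max(norm)
    return ExpressionSeries(gene=gene, species=species, stages=tuple(stages),
                            raw=list(raw), normalized=norm,
                            percent_of_max=pct, silent=silent)


def celltype_ratio(gene, species, prespore_count, prestalk_count) -> CellTypeRatio:
    """Prespore/prestalk percentages of the summed cell-type counts."""
    if prespore_count < 0 or prestalk_count < 0:
        raise ValueError("counts must be >= 0")
    total = prespore_count + prestalk_count
    if total == 0:
        return CellTypeRatio(gene, species, 0.0, 0.0, undefined=True)
    return CellTypeRatio(gene, species,
                         100.0 * prespore_count / total,
                         100.0 * prestalk_count / total)


def profile_distance(profile_a, profile_b) -> float:
    """Mean absolute percent-of-max difference, scaled into [0, 1].

    A silent series (all zeros) versus an expressed one is maximally
    distant (1); two silent series are identical (0).
    """
    a, b = list(profile_a), list(profile_b)
    if len(a) != len(b):
        raise ValueError(f"profile length mismatch: {len(a)} vs {len(b)}")
    silent_a = max(a, default=0) <= 0
    silent_b = max(b, default=0) <= 0
    if silent_a and silent_b:
        return 0.0
    if silent_a or silent_b:
        return 1.0
    return sum(abs(x - y) for x, y in zip(a, b)) / (100.0 * len(a))


def _pattern_from_flags(flagged: frozenset) -> str:
    if not flagged:
        return "conserved"
    if len(flagged) == 1:
        return "one_species"
    if flagged == GROUP4 or flagged == frozenset({"DL", "PP", "DF"}):
        return "group4_vs_123"
    if flagged == BRANCH_I or flagged == BRANCH_II:
        return "branchI_vs_II"
    return "other"


def call_divergence(profiles_by_species: dict, theta: float = DEFAULT_THETA,
                    gene: str = "") -> DivergenceResult:
    """Flag divergently expressed species and name the phylogenetic pattern.

    Species are grouped by single linkage at distance ``theta``; the
    largest group is the reference (majority) expression pattern.
    A species outside the reference is flagged divergent when its
    profile differs (> theta) from at least two other species — the
    criterion that a profile must clearly differ from at least two
    others before a gene counts as differentially regulated.
    """
    species = sorted(profiles_by_species)
    if len(species) < 3:
        raise ValueError("divergence calling needs profiles for >= 3 species")
    dist = {}
    for i, s in enumerate(species):
        for t in species[i + 1:]:
            d = profile_distance(profiles_by_species[s], profiles_by_species[t])
            dist[(s, t)] = dist[(t, s)] = d

    # single-linkage components at threshold theta
    comp = {s: s for s in species}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for (s, t), d in dist.items():
        if d <= theta:
            comp[find(s)] = find(t)
    groups: dict[str, list] = {}
    for s in species:
        groups.setdefault(find(s), []).append(s)
    reference = set(max(sorted(groups.values()), key=len))

    flagged = set()
    for s in species:
        if s in reference:
            continue
        n_diff = sum(1 for t in species if t != s and dist[(s, t)] > theta)
        if n_diff >= 2:
            flagged.add(s)
    flags = tuple((s, s in flagged) for s in species)
    return DivergenceResult(gene=gene, flags=flags,
                            pattern=_pattern_from_flags(frozenset(flagged)),
                            theta=theta)


def stage_match(time_series: dict, stage_map: dict, stages=STAGES) -> list[float]:
    """Collapse an arbitrary time course onto the canonical stages.

    ``time_series`` maps source time points/labels to values;
    ``stage_map`` assigns each source point to one canonical stage.
    Multiple source points per stage are averaged (before any
    percent-of-max rescaling).  A canonical stage with no mapped source
    point is an error naming the gap.
    """
    buckets: dict[str, list] = {s: [] for s in stages}
    for point, value in time_series.items():
        if point not in stage_map:
            raise ValueError(f"source point '{point}' missing from stage map")
        stage = stage_map[point]
        if stage not in buckets:
            raise ValueError(f"stage map targets unknown stage '{stage}'")
        buckets[stage].append(value)
    gaps = [s for s in stages if not buckets[s]]
    if gaps:
        raise ValueError(f"no source points mapped to stage(s): {', '.join(gaps)}")
    return [sum(buckets[s]) / len(buckets[s]) for s in stages]
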
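"""Multi-areas genetic algorithm: find all local minima of epsilon(theta) at once.

A classical GA hunts one global optimum; here every compound in the mixture
leaves its own local minimum on the (mu, sigma) fitness surface, and all of
them must be found in one run. The population is therefore clustered each
generation into "areas" — circles in the (mu, sigma) plane grown greedily
around the fittest unassigned chromosome — and evolution happens inside
areas: elites mate with their most dissimilar (maximum Hamming distance)
area-mate and children are generated by flipping each differing bit;
children that beat a parent replace the area's inferior members. Only a few
top chromosomes stay in each area; the rest emigrate, and an immigration
quota — inversely proportional to how many elites an area already has, with
severely overlapping areas merged into one receiving group and
boundary-centred areas ignored — refills the population with fresh random
chromosomes drawn inside each area's circle. The run ends when no area's
radius is large enough to keep reproducing; each final area centre that is
an 8-neighbour local minimum of the fitness grid is a solution.

Chromosomes encode (mu, sigma) as plain binary, mu-then-sigma, with fixed
widths ceil(log2(t)) and ceil(log2(sigma_max)). All distances between
chromosomes are Euclidean in (mu, sigma) units. Ties are broken everywhere
by (fitness, mu, sigma), so a run is fully reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Chromatogram3D
from .model import FitOptions, FitnessCache, fitness
from .preprocess import WhitenedData, center_whiten
from .reference import ReferenceParams, bit_widths, sigma_max

logger = logging.getLogger(__name__)

__all__ = [
    "Chromosome",
    "Area",
    "MGAConfig",
    "MGAResult",
    "encode",
    "decode",
    "init_population",
    "separate_areas",
    "mate_and_reproduce",
    "select_emigrants",
    "allocate_immigrants",
    "find_solutions",
    "run",
]


@dataclass(frozen=True)
class Chromosome:
    bits: str
    theta: ReferenceParams
    fit: float

    @property
    def sort_key(self) -> tuple:
        return (self.fit, self.theta.mu, self.theta.sigma)


@dataclass
class Area:
    """A circle of nearby chromosomes; its centre is a candidate solution."""

    center: Chromosome
    radius: float
    members: list[Chromosome]
    num_elites: int = 0
    num_pop: int = 0
    merged_group: int | None = None
    at_boundary: bool = False


@dataclass
class MGAConfig:
    """Search parameters; defaults sized for a 241-point, few-compound run."""

    pop_size: int = 60
    n_subspaces: int = 6
    n_elites_per_area: int = 5
    keep_per_area: int = 3
    initial_radius: float = 5.0
    radius_stop_threshold: float = 1.5
    overlap_merge_factor: float = 1.0
    max_generations: int = 50
    seed: int = 0
    strict_child_filter: bool = False
    # Fraction of the population reserved for immigrants each generation.
    # Without it, once there are pop_size / keep_per_area areas every
    # chromosome is a stayer, immigration stops and the search stagnates;
    # the reserve evicts the globally worst stayers (extra emigrants), so
    # low-fitness straggler areas die out and the flux of fresh chromosomes
    # into the real basins never dries up.
    immigrant_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "pop_size", "n_subspaces", "n_elites_per_area", "keep_per_area",
            "initial_radius", "radius_stop_threshold", "overlap_merge_factor",
            "max_generations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.immigrant_fraction < 1.0:
            raise ValueError("immigrant_fraction must be in [0, 1)")


@dataclass
class MGAResult:
    solutions: list[ReferenceParams]
    areas_final: list[Area]
    generations: int
    history: list[dict] = field(default_factory=list)
    hit_max_generations: bool = False
    cache: FitnessCache | None = None


def encode(theta: ReferenceParams, t: int) -> str:
    """Fixed-width binary encoding of (mu-1, sigma-1), mu bits first."""
    theta.validate(t)
    wmu, wsig = bit_widths(t)
    return format(theta.mu - 1, f"0{wmu}b") + format(theta.sigma - 1, f"0{wsig}b")


def decode(bits: str, t: int) -> ReferenceParams:
    """Inverse of :func:`encode`; raises ``ValueError`` for off-grid bit patterns."""
    wmu, wsig = bit_widths(t)
    if len(bits) != wmu + wsig or set(bits) - {"0", "1"}:
        raise ValueError(f"bad chromosome bits {bits!r}")
    theta = ReferenceParams(int(bits[:wmu], 2) + 1, int(bits[wmu:], 2) + 1)
    theta.validate(t)
    return theta


def _distance(a: ReferenceParams, b: ReferenceParams) -> float:
    return float(np.hypot(a.mu - b.mu, a.sigma - b.sigma))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _Evaluator:
    """Builds chromosomes with memoised fitness evaluation."""

    def __init__(self, W: WhitenedData, opts: FitOptions, cache: FitnessCache):
        self.W = W
        self.opts = opts
        self.cache = cache
        self.t = W.t

    def make(self, theta: ReferenceParams) -> Chromosome:
        return Chromosome(
            bits=encode(theta, self.t),
            theta=theta,
            fit=fitness(theta, self.W, self.opts, self.cache),
        )


def init_population(
    W: WhitenedData,
    cfg: MGAConfig,
    n_subspaces: int | None = None,
    opts: FitOptions | None = None,
    cache: FitnessCache | None = None,
    rng: np.random.Generator | None = None,
) -> list[Chromosome]:
    """Stratified random initialisation: sample each mu-slice, keep the global best.

    The mu axis is split into ``n_subspaces`` equal intervals; ``pop_size``
    chromosomes are drawn uniformly in each, and the overall top ``pop_size``
    by fitness become the initial population. Stratifying guarantees that
    even a basin far from the dominant peak gets sampled.
    """
    n_sub = n_subspaces if n_subspaces is not None else cfg.n_subspaces
    ev = _Evaluator(W, opts or FitOptions(), cache if cache is not None else FitnessCache())
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t = W.t
    smax = sigma_max(t)
    edges = np.linspace(1, t + 1, n_sub + 1)
    pool: list[Chromosome] = []
    for i in range(n_sub):
        lo, hi = int(np.floor(edges[i])), int(np.floor(edges[i + 1])) - 1
        hi = max(lo, min(hi, t))
        mus = rng.integers(lo, hi + 1, size=cfg.pop_size)
        sigs = rng.integers(1, smax + 1, size=cfg.pop_size)
        pool.extend(ev.make(ReferenceParams(int(m), int(s))) for m, s in zip(mus, sigs))
    pool.sort(key=lambda c: c.sort_key)
    return pool[: cfg.pop_size]


def separate_areas(pop: list[Chromosome], r0: float) -> list[Area]:
    """Greedy clustering: the fittest unassigned chromosome seeds each circle.

    All unassigned chromosomes within ``r0`` of the seed join; the area's
    radius becomes the largest member distance (0 for a singleton). Every
    chromosome ends up in exactly one area.
    """
    if not pop:
        raise ValueError("empty population")
    remaining = sorted(pop, key=lambda c: c.sort_key)
    areas: list[Area] = []
    while remaining:
        center = remaining[0]
        members = [c for c in remaining if _distance(c.theta, center.theta) <= r0]
        radius = max(_distance(c.theta, center.theta) for c in members)
        areas.append(
            Area(center=center, radius=radius, members=members, num_pop=len(members))
        )
        taken = set(id(c) for c in members)
        remaining = [c for c in remaining if id(c) not in taken]
    return areas


def mate_and_reproduce(
    area: Area, cfg: MGAConfig, ev: _Evaluator
) -> list[Chromosome]:
    """Elite mating by maximum Hamming distance; one child per differing bit.

    Each of the area's top ``n_elites_per_area`` chromosomes mates with the
    member most dissimilar to it in bit space (ties broken by fitness
    order). Each differing bit position yields one child: the elite with
    that bit copied from the mate. A child is accepted when it beats the
    worse parent (or both parents with ``strict_child_filter``).
    """
    members = sorted(area.members, key=lambda c: c.sort_key)
    if len(members) < 2:
        return []
    elites = members[: cfg.n_elites_per_area]
    accepted: list[Chromosome] = []
    seen: set[str] = {c.bits for c in members}
    for elite in elites:
        mate = max(
            (c for c in members if c is not elite),
            key=lambda c: (_hamming(elite.bits, c.bits), -members.index(c)),
        )
        if elite.bits == mate.bits:
            continue
        threshold = (
            min(elite.fit, mate.fit) if cfg.strict_child_filter
            else max(elite.fit, mate.fit)
        )
        for p, (be, bm) in enumerate(zip(elite.bits, mate.bits)):
            if be == bm:
                continue
            child_bits = elite.bits[:p] + bm + elite.bits[p + 1 :]
            if child_bits in seen:
                continue
            seen.add(child_bits)
            try:
                theta = decode(child_bits, ev.t)
            except ValueError:
                continue  # off-grid bit pattern
            child = ev.make(theta)
            if child.fit < threshold:
                accepted.append(child)
    return accepted


def select_emigrants(area: Area, keep: int) -> tuple[list[Chromosome], list[Chromosome]]:
    """Top ``keep`` members by fitness stay; the rest become emigrants."""
    if keep < 1:
        raise ValueError("keep must be >= 1")
    members = sorted(area.members, key=lambda c: c.sort_key)
    return members[:keep], members[keep:]


def _merge_overlapping(areas: list[Area], factor: float) -> list[list[Area]]:
    """Transitive closure of the 'severely overlapped' relation on areas."""
    n = len(areas)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = _distance(areas[i].center.theta, areas[j].center.theta)
            if d < factor * (areas[i].radius + areas[j].radius):
                parent[find(i)] = find(j)
    groups: dict[int, list[Area]] = {}
    for i, a in enumerate(areas):
        groups.setdefault(find(i), []).append(a)
    return list(groups.values())


def allocate_immigrants(
    areas: list[Area], total_quota: int, cfg: MGAConfig, t: int
) -> list[tuple[list[Area], int]]:
    """Group areas and allocate the immigration quota among groups.

    Boundary-centred areas are excluded; severely overlapping areas (centre
    distance < ``overlap_merge_factor`` x sum of radii, transitively) merge
    into one receiving group; each group's quota is proportional to
    1/(1 + elites in group), rounded by largest remainder so the quotas sum
    exactly to ``total_quota``. Immigrants keep refining even areas too
    small to reproduce: a frozen area's centre can still be displaced by a
    fitter immigrant landing inside its circle, which is how a centre one
    step off a fitness minimum slides onto it.
    """
    if total_quota < 0:
        raise ValueError("total_quota must be >= 0")
    for a in areas:
        a.at_boundary = a.center.theta.on_boundary(t)
    eligible = [a for a in areas if not a.at_boundary]
    if not eligible or total_quota == 0:
        return []
    groups = _merge_overlapping(eligible, cfg.overlap_merge_factor)
    for gid, group in enumerate(groups):
        for a in group:
            a.merged_group = gid
    weights = np.array([1.0 / (1 + sum(a.num_elites for a in g)) for g in groups])
    raw = total_quota * weights / weights.sum()
    quotas = np.floor(raw).astype(int)
    remainder = raw - quotas
    short = total_quota - quotas.sum()
    # Largest remainder; ties resolved toward the better (lower-fitness) group.
    order = sorted(
        range(len(groups)),
        key=lambda i: (-remainder[i], min(a.center.fit for a in groups[i])),
    )
    for i in order[:short]:
        quotas[i] += 1
    return [(g, int(q)) for g, q in zip(groups, quotas)]


def _group_circle(group: list[Area]) -> tuple[ReferenceParams, float]:
    """Sampling circle of a receiving group: best centre, largest member radius.

    A merged group's areas are severely overlapped, so immigrants drawn
    around the best centre serve every member area. Using the largest area
    radius (not a full enclosing radius) lets the sampling circle contract
    as the areas themselves contract, which is what drives termination.
    """
    best = min(group, key=lambda a: a.center.sort_key)
    return best.center.theta, max(a.radius for a in group)


def generate_immigrants(
    allocation: list[tuple[list[Area], int]],
    cfg: MGAConfig,
    ev: _Evaluator,
    rng: np.random.Generator,
    all_areas: list[Area] | None = None,
) -> list[Chromosome]:
    """Draw candidates inside each group's circle; keep the fittest per quota.

    Mirrors the initialisation scheme: ``pop_size`` random chromosomes are
    generated per group (uniform in the sampling circle, clipped to the
    grid), and only the top ``quota`` by fitness immigrate. A candidate that
    falls inside the circle of a fitter area outside the group is not this
    group's immigrant — at the next separation it would be captured by that
    area anyway, inflating its radius instead of serving its own — and is
    discarded before selection.
    """
    t, smax = ev.t, sigma_max(ev.t)
    immigrants: list[Chromosome] = []
    for group, quota in allocation:
        if quota <= 0:
            continue
        center, radius = _group_circle(group)
        radius = max(radius, 1.0)  # a point-circle still admits its neighbours
        best_fit = min(a.center.fit for a in group)
        in_group = set(map(id, group))
        captors = [
            a for a in (all_areas or [])
            if id(a) not in in_group and a.center.fit < best_fit
        ]
        angles = rng.uniform(0, 2 * np.pi, size=cfg.pop_size)
        radii = radius * np.sqrt(rng.uniform(0, 1, size=cfg.pop_size))
        mus = np.clip(np.rint(center.mu + radii * np.cos(angles)), 1, t).astype(int)
        sigs = np.clip(np.rint(center.sigma + radii * np.sin(angles)), 1, smax).astype(int)
        cands = []
        for m, s in zip(mus, sigs):
            th = ReferenceParams(int(m), int(s))
            if any(
                _distance(th, a.center.theta) <= cfg.initial_radius for a in captors
            ):
                continue
            cands.append(ev.make(th))
        cands.sort(key=lambda c: c.sort_key)
        immigrants.extend(cands[:quota])
    return immigrants


def find_solutions(
    centers: list[Chromosome],
    W: WhitenedData,
    opts: FitOptions | None = None,
    cache: FitnessCache | None = None,
) -> list[ReferenceParams]:
    """Keep each centre that is an interior 8-neighbour local minimum of epsilon.

    A centre theta qualifies when epsilon(theta) <= epsilon(theta') for all
    8 grid neighbours (clipped to the domain) and theta is not on the domain
    boundary. Duplicates collapse to one solution; the result is sorted by
    ascending (mu, sigma).
    """
    opts = opts or FitOptions()
    cache = cache if cache is not None else FitnessCache()
    t = W.t
    smax = sigma_max(t)
    solutions: set[ReferenceParams] = set()
    for c in centers:
        th = c.theta
        if th.on_boundary(t):
            continue
        eps0 = fitness(th, W, opts, cache)
        is_min = True
        for dmu in (-1, 0, 1):
            for dsig in (-1, 0, 1):
                if dmu == 0 and dsig == 0:
                    continue
                nb = ReferenceParams(th.mu + dmu, th.sigma + dsig)
                if not (1 <= nb.mu <= t and 1 <= nb.sigma <= smax):
                    continue
                if fitness(nb, W, opts, cache) < eps0:
                    is_min = False
                    break
            if not is_min:
                break
        if is_min:
            solutions.add(th)
    return sorted(solutions, key=lambda th: (th.mu, th.sigma))


def _area_history(gen: int, areas: list[Area]) -> list[dict]:
    return [
        {
            "Generation": gen,
            "AreaId": i + 1,
            "CenterMu": a.center.theta.mu,
            "CenterSigma": a.center.theta.sigma,
            "Radius": round(a.radius, 4),
            "NumE": a.num_elites,
            "NumP": a.num_pop,
            "BestFit": a.center.fit,
        }
        for i, a in enumerate(areas)
    ]


def run(
    X: Chromatogram3D | np.ndarray,
    cfg: MGAConfig | None = None,
    fit_opts: FitOptions | None = None,
) -> MGAResult:
    """Run the full multi-areas search on a chromatogram matrix.

    Whitens once, evolves the population until no area's radius exceeds the
    reproduction threshold (or ``max_generations``), then screens the final
    area centres for genuine grid local minima. Fully reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or MGAConfig()
    fit_opts = fit_opts or FitOptions()
    W = center_whiten(X)
    cache = FitnessCache()
    ev = _Evaluator(W, fit_opts, cache)
    rng = np.random.default_rng(cfg.seed)

    pop = init_population(W, cfg, cfg.n_subspaces, fit_opts, cache, rng)
    history: list[dict] = []
    areas: list[Area] = []
    hit_max = False
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        areas = separate_areas(pop, cfg.initial_radius)
        for a in areas:
            a.num_elites = min(cfg.n_elites_per_area, len(a.members))
        history.extend(_area_history(gen, areas))
        logger.info(
            "generation %d: %d areas, best fit %.3e",
            gen, len(areas), areas[0].center.fit,
        )
        can_reproduce = [
            a for a in areas
            if a.radius > cfg.radius_stop_threshold and len(a.members) >= 2
        ]
        if not can_reproduce:
            break
        for a in can_reproduce:
            children = mate_and_reproduce(a, cfg, ev)
            if children:
                merged = sorted(a.members + children, key=lambda c: c.sort_key)
                a.members = merged[: len(a.members)]  # children replace the inferior
                a.center = a.members[0]
                a.radius = max(_distance(c.theta, a.center.theta) for c in a.members)
        for a in areas:
            stay, _ = select_emigrants(a, cfg.keep_per_area)
            a.members = stay
            a.num_pop = len(stay)
        min_quota = int(np.ceil(cfg.immigrant_fraction * cfg.pop_size))
        n_stay_max = cfg.pop_size - min_quota
        n_staying = sum(len(a.members) for a in areas)
        if n_staying > n_stay_max:
            # Extra emigrants: evict the globally worst stayers so the
            # immigrant reserve is honoured; emptied areas disappear.
            cut = sorted(
                (c for a in areas for c in a.members), key=lambda c: c.sort_key
            )[:n_stay_max]
            keep_ids = {id(c) for c in cut}
            for a in areas:
                a.members = [c for c in a.members if id(c) in keep_ids]
                a.num_pop = len(a.members)
            areas = [a for a in areas if a.members]
            for a in areas:
                a.center = min(a.members, key=lambda c: c.sort_key)
        stayers = [c for a in areas for c in a.members]
        total_quota = max(0, cfg.pop_size - len(stayers))
        allocation = allocate_immigrants(areas, total_quota, cfg, W.t)
        immigrants = generate_immigrants(allocation, cfg, ev, rng, all_areas=areas)
        pop = stayers + immigrants
    else:
        hit_max = True
        logger.warning("max_generations=%d reached before convergence", cfg.max_generations)
        areas = separate_areas(pop, cfg.initial_radius)
        for a in areas:
            a.num_elites = min(cfg.n_elites_per_area, len(a.members))

    solutions = find_solutions([a.center for a in areas], W, fit_opts, cache)
    return MGAResult(
        solutions=solutions,
        areas_final=areas,
        generations=gen,
        history=history,
        hit_max_generations=hit_max,
        cache=cache,
    )
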
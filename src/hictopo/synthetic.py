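"""Synthetic Hi-C contact maps with planted, recorded structure.

The generator plants the four structures the downstream pipeline
measures — power-law distance decay, TAD blocks with insulating
boundaries, an alternating A/B plaid, and focal loops — draws Poisson
counts around the resulting intensity surface, and applies two
perturbation models:

``rnase_like``
    attenuates the plaid contribution of B-B bin pairs by a factor
    ``f_bb`` — in cis only beyond ``bb_min_dist`` (the phenotype is a
    loss of *long-range* B-type compartmental interactions; short-range
    contacts, which dominate balancing marginals, are untouched), in
    trans everywhere. TAD structure is untouched;
``actd_like``
    moves boundary permeabilities toward 1 and scales loop enrichments
    toward 1 (TAD boundaries and loops weaken; the compartment profile
    is untouched).

Every planted quantity is recorded in a :class:`SyntheticTruth` so
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .bins import BinTable, make_bins
from .matrix_io import ContactMatrix

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "IntensityModel",
    "plant_truth",
    "simulate_contacts",
    "apply_perturbation",
    "save_truth",
    "load_truth",
]


@dataclass
class GeneratorConfig:
    """Desk-scale study conditions for the synthetic generator.

    Defaults describe a two-chromosome 2 x 20 Mb genome with unit decay
    exponent, 2e6 expected cis counts per chromosome, ~1 Mb TADs with
    strongly insulating boundaries, 5 Mb alternating A/B blocks, and 40
    focal loops at 3-fold enrichment. All sizes in bp.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    alpha: float = 1.0                      # decay exponent, P(s) ~ s^-alpha
    depth: float = 2_000_000.0              # expected cis counts/chromosome (|i-j| >= 2)
    trans_depth: float = 400_000.0          # expected counts per chromosome pair
    # TADs
    with_tads: bool = True
    tad_size_mean: int = 1_000_000
    tad_size_min: int = 600_000   # > insulation square + smoothing, so boundaries stay resolvable
    tad_boost: float = 2.0                  # within-TAD intensity multiplier
    boundary_permeability: float = 0.2      # cross-boundary attenuation, in (0, 1]
    insulation_range: int = 1_200_000       # bp; boundary attenuation acts below this separation
    # compartments
    plaid_strength: float = 0.4             # scale of exp(plaid * c_i * c_j)
    compartment_block_mean: int = 5_000_000
    compartment_block_min: int = 2_000_000
    compartment_strength: tuple[float, float] = (1.0, 1.0)  # |c| drawn per block (default: two-level +-1 profile)
    # loops
    n_loops: int = 40
    loop_enrichment: float = 3.0            # >= 1, multiplier at the loop pixel
    loop_min_sep: int = 1_500_000
    loop_max_sep: int = 5_000_000


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic genome at one resolution."""

    chrom_sizes: dict[str, int]
    resolution: int
    alpha: float
    tad_boundaries: np.ndarray            # global bin indices (domain left edges)
    tad_boost: float
    boundary_permeability: np.ndarray     # per boundary, in (0, 1]
    compartment_profile: np.ndarray       # per bin; sign = A/B, magnitude = strength
    plaid_strength: float
    loops: list[tuple[int, int, float]]   # (bin_a, bin_b, enrichment), bin_a < bin_b
    depth: float
    trans_depth: float
    seed: int
    bb_attenuation: float = 1.0           # rnase_like multiplier on long-range B-B plaid
    bb_min_dist: int = 2_000_000          # bp; cis B-B attenuation applies at/beyond this separation
    insulation_range: int = 1_200_000     # bp; boundary attenuation acts below this separation

    def __post_init__(self):
        self.tad_boundaries = np.asarray(self.tad_boundaries, dtype=np.int64)
        self.boundary_permeability = np.asarray(self.boundary_permeability, dtype=float)
        self.compartment_profile = np.asarray(self.compartment_profile, dtype=float)
        if self.tad_boundaries.size != self.boundary_permeability.size:
            raise ValueError("one permeability per boundary required")
        if np.any(np.diff(self.tad_boundaries) <= 0):
            raise ValueError("tad_boundaries must be strictly increasing")
        if np.any((self.boundary_permeability <= 0) | (self.boundary_permeability > 1)):
            raise ValueError("boundary permeabilities must lie in (0, 1]")
        if self.tad_boost <= 0 or self.alpha <= 0:
            raise ValueError("multipliers and alpha must be positive")
        for a, b, e in self.loops:
            if not a < b:
                raise ValueError(f"loop anchors must satisfy bin_a < bin_b, got ({a}, {b})")
            if e < 1:
                raise ValueError(f"loop enrichment must be >= 1, got {e}")

    def bin_table(self) -> BinTable:
        return make_bins(self.chrom_sizes, self.resolution)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.chrom_sizes == other.chrom_sizes
            and self.resolution == other.resolution
            and np.isclose(self.alpha, other.alpha)
            and np.array_equal(self.tad_boundaries, other.tad_boundaries)
            and np.isclose(self.tad_boost, other.tad_boost)
            and np.allclose(self.boundary_permeability, other.boundary_permeability)
            and np.allclose(self.compartment_profile, other.compartment_profile)
            and np.isclose(self.plaid_strength, other.plaid_strength)
            and len(self.loops) == len(other.loops)
            and all(a == c and b == d and np.isclose(e, f)
                    for (a, b, e), (c, d, f) in zip(self.loops, other.loops))
            and np.isclose(self.depth, other.depth)
            and np.isclose(self.trans_depth, other.trans_depth)
            and self.seed == other.seed
            and np.isclose(self.bb_attenuation, other.bb_attenuation)
        )


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _draw_change_points(rng, length_bp, mean_bp, min_bp):
    """Segment a chromosome into blocks with sizes uniform on
    [min, 2*mean - min] (mean block size = ``mean_bp``, bounded so no
    single block can swallow the chromosome)."""
    hi = max(2 * mean_bp - min_bp, min_bp + 1)
    points, pos = [], 0.0
    while True:
        pos += rng.uniform(min_bp, hi)
        if pos >= length_bp - min_bp:
            break
        points.append(int(pos))
    return points


def plant_truth(bins: BinTable, config: GeneratorConfig, seed: int) -> SyntheticTruth:
    """Draw planted structure for ``bins``; deterministic given ``seed``.

    TAD and compartment block positions are drawn in bp and snapped to
    bin edges. Raises ``ValueError`` if the configured minimum TAD size
    is below 3 bins (boundary calling is undefined there) or compartment
    blocks below 2 bins.
    """
    res = bins.resolution
    if config.with_tads and config.tad_size_min < 3 * res:
        raise ValueError(
            f"minimum TAD size {config.tad_size_min} < 3 bins at {res} bp resolution")
    if config.compartment_block_min < 2 * res:
        raise ValueError(
            f"minimum compartment block {config.compartment_block_min} < 2 bins at {res} bp")

    rng = np.random.default_rng(seed)
    boundaries, perms = [], []
    profile = np.zeros(len(bins))
    loops: list[tuple[int, int, float]] = []
    lo, hi = config.compartment_strength

    for chrom, size in config.chrom_sizes.items():
        offset = bins.chrom_offset(chrom)
        nc = bins.n_chrom_bins(chrom)
        # TAD boundaries: left edge of each new domain
        chrom_tads: list[int] = []
        if config.with_tads:
            for pos in _draw_change_points(rng, size, config.tad_size_mean, config.tad_size_min):
                b = pos // res
                if chrom_tads and b == chrom_tads[-1]:
                    continue
                chrom_tads.append(b)
                boundaries.append(offset + b)
                perms.append(config.boundary_permeability)
        # compartment blocks, alternating sign; block edges snap to the
        # nearest TAD boundary (compartment transitions coincide with
        # domain boundaries, so their insulation dips reinforce rather
        # than compete with planted boundaries)
        sign = rng.choice([-1.0, 1.0])
        raw_edges = [p // res for p in _draw_change_points(
            rng, size, config.compartment_block_mean, config.compartment_block_min)]
        if chrom_tads:
            tad_arr = np.array(chrom_tads)
            raw_edges = [int(tad_arr[np.abs(tad_arr - e).argmin()]) for e in raw_edges]
        raw_edges = sorted({e for e in raw_edges if 0 < e < nc})
        edges = [0] + raw_edges + [nc]
        for k in range(len(edges) - 1):
            profile[offset + edges[k]: offset + edges[k + 1]] = sign * rng.uniform(lo, hi)
            sign = -sign
        # loops (cis, away from chromosome ends so pileup windows fit)
        if config.n_loops > 0:
            margin = 12
            n_here = config.n_loops // len(config.chrom_sizes)
            min_sep = max(config.loop_min_sep // res, 1)
            max_sep = max(config.loop_max_sep // res, min_sep + 1)
            seen = set()
            attempts = 0
            while len(seen) < n_here and attempts < 50 * n_here:
                attempts += 1
                d = int(rng.integers(min_sep, max_sep + 1))
                if nc - 2 * margin - d <= 0:
                    continue
                a = int(rng.integers(margin, nc - margin - d))
                pair = (offset + a, offset + a + d)
                if pair not in seen:
                    seen.add(pair)
            loops.extend((a, b, float(config.loop_enrichment)) for a, b in sorted(seen))

    return SyntheticTruth(
        chrom_sizes=dict(config.chrom_sizes),
        resolution=res,
        alpha=config.alpha,
        tad_boundaries=np.array(boundaries, dtype=np.int64),
        tad_boost=config.tad_boost if config.with_tads else 1.0,
        boundary_permeability=np.array(perms, dtype=float),
        compartment_profile=profile,
        plaid_strength=config.plaid_strength,
        loops=loops,
        depth=config.depth,
        trans_depth=config.trans_depth,
        seed=int(seed),
        insulation_range=config.insulation_range,
    )


# ---------------------------------------------------------------------------
# Intensity surface
# ---------------------------------------------------------------------------

class IntensityModel:
    """Expected-count surface lambda(i, j) implied by a planted truth.

    Cis: depth-scaled product of a decay term ``|i-j|^-alpha``, a TAD
    term (``tad_boost`` within a domain, product of crossed-boundary
    permeabilities otherwise), a plaid term ``exp(plaid * c_i * c_j)``
    (times ``bb_attenuation`` when both bins are B-type) and a loop term
    (full enrichment at the loop pixel, half the excess on the 3x3 halo).
    The per-chromosome scale is set so cis pixels at separation >= 2 bins
    sum to ``depth``. Trans blocks carry a constant mean modulated by the
    same plaid term, summing to ``trans_depth`` per chromosome pair.
    """

    def __init__(self, truth: SyntheticTruth, bins: BinTable | None = None):
        self.truth = truth
        self.bins = bins if bins is not None else truth.bin_table()
        if (self.bins.chrom_sizes != truth.chrom_sizes
                or self.bins.resolution != truth.resolution):
            raise ValueError("bin table inconsistent with truth")

    def _plaid(self, c_row: np.ndarray, c_col: np.ndarray,
               attenuate: np.ndarray | bool = True) -> np.ndarray:
        # ``attenuate`` selects the pixels eligible for the B-B
        # attenuation: all of trans, only long-range cis
        t = self.truth
        term = np.exp(t.plaid_strength * np.outer(c_row, c_col))
        if t.bb_attenuation != 1.0:
            bb = np.outer(c_row < 0, c_col < 0) & attenuate
            term[bb] *= t.bb_attenuation
        return term

    def cis(self, chrom: str) -> np.ndarray:
        t = self.truth
        sl = self.bins.chrom_slices[chrom]
        nc = sl.stop - sl.start
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        decay = np.where(d >= 1, np.maximum(d, 1.0) ** (-t.alpha), 1.0)

        local_b = t.tad_boundaries[(t.tad_boundaries >= sl.start)
                                   & (t.tad_boundaries < sl.stop)] - sl.start
        local_p = t.boundary_permeability[(t.tad_boundaries >= sl.start)
                                          & (t.tad_boundaries < sl.stop)]
        dom = np.searchsorted(local_b, idx, side="right")
        cum = np.concatenate([[0.0], np.cumsum(np.log(local_p))])
        cross = np.exp(-np.abs(cum[dom][:, None] - cum[dom][None, :]))
        # boundary insulation is local: beyond insulation_range the
        # contact frequency reverts to decay x compartments
        in_range = d <= t.insulation_range / self.bins.resolution
        same = dom[:, None] == dom[None, :]
        tad = np.where(same, t.tad_boost, np.where(in_range, cross, 1.0))

        c = t.compartment_profile[sl]
        far_bb = d >= t.bb_min_dist / self.bins.resolution
        lam = decay * tad * self._plaid(c, c, attenuate=far_bb)

        for a, b, e in t.loops:
            if not (sl.start <= a < sl.stop and sl.start <= b < sl.stop):
                continue
            la, lb = a - sl.start, b - sl.start
            halo = 1.0 + (e - 1.0) / 2.0
            r0, r1 = max(la - 1, 0), min(la + 2, nc)
            c0, c1 = max(lb - 1, 0), min(lb + 2, nc)
            lam[r0:r1, c0:c1] *= halo
            lam[c0:c1, r0:r1] *= halo
            lam[la, lb] *= e / halo
            lam[lb, la] *= e / halo

        far = d >= 2
        # depth counts each unordered pair once; lam[far] covers both triangles
        scale = t.depth / (lam[far].sum() / 2.0)
        return lam * scale

    def trans(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        t = self.truth
        sa, sb = self.bins.chrom_slices[chrom_a], self.bins.chrom_slices[chrom_b]
        lam = self._plaid(t.compartment_profile[sa], t.compartment_profile[sb])
        return lam * (t.trans_depth / lam.sum())

    def dense(self) -> np.ndarray:
        """Genome-wide expected-count matrix (cis blocks + trans blocks)."""
        n = len(self.bins)
        lam = np.zeros((n, n))
        chroms = self.bins.chroms
        for i, ca in enumerate(chroms):
            sa = self.bins.chrom_slices[ca]
            lam[sa, sa] = self.cis(ca)
            for cb in chroms[i + 1:]:
                sb = self.bins.chrom_slices[cb]
                block = self.trans(ca, cb)
                lam[sa, sb] = block
                lam[sb, sa] = block.T
        return lam


def simulate_contacts(truth: SyntheticTruth, bins: BinTable, seed: int) -> ContactMatrix:
    """Draw an observed contact matrix: independent Poisson counts with
    mean ``lambda(i, j)``, symmetrized, reproducible given ``seed``.

    Diagonal and first off-diagonal pixels are generated but are flagged
    for downstream masking (``meta['exclude_diags'] = 2``), mirroring
    the standard exclusion of self/adjacent-ligation signal.
    """
    model = IntensityModel(truth, bins)
    lam = model.dense()
    rng = np.random.default_rng(seed)
    n = len(bins)
    iu, ju = np.triu_indices(n)
    draws = rng.poisson(lam[iu, ju]).astype(float)
    counts = np.zeros((n, n))
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return ContactMatrix(bins, counts, meta={
        "seed": int(seed), "exclude_diags": 2, "space": "counts"})


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(truth: SyntheticTruth, kind: str, **params) -> SyntheticTruth:
    """Return a perturbed copy of ``truth``; the input is not modified.

    ``rnase_like(f_bb)``: multiply the plaid contribution of B-B pairs
    by ``f_bb`` in (0, 1]. TAD boundaries, permeabilities and loops are
    untouched.

    ``actd_like(permeability_rescue, loop_retain)``: move each boundary
    permeability the fraction ``permeability_rescue`` of the way to 1
    (1.0 erases all insulation) and retain the fraction ``loop_retain``
    of each loop's enrichment above background. The compartment profile
    and plaid strength are untouched.
    """
    new = dataclasses.replace(
        truth,
        tad_boundaries=truth.tad_boundaries.copy(),
        boundary_permeability=truth.boundary_permeability.copy(),
        compartment_profile=truth.compartment_profile.copy(),
        loops=list(truth.loops),
    )
    if kind == "rnase_like":
        f_bb = float(params.pop("f_bb", 0.7))
        if params:
            raise ValueError(f"unknown rnase_like parameters: {sorted(params)}")
        if not 0 < f_bb <= 1:
            raise ValueError(f"f_bb must be in (0, 1], got {f_bb}")
        new.bb_attenuation = truth.bb_attenuation * f_bb
    elif kind == "actd_like":
        rescue = float(params.pop("permeability_rescue", 0.5))
        retain = float(params.pop("loop_retain", 0.5))
        if params:
            raise ValueError(f"unknown actd_like parameters: {sorted(params)}")
        if not 0 <= rescue <= 1 or not 0 <= retain <= 1:
            raise ValueError("permeability_rescue and loop_retain must lie in [0, 1]")
        p = truth.boundary_permeability
        new.boundary_permeability = p + rescue * (1.0 - p)
        new.loops = [(a, b, 1.0 + retain * (e - 1.0)) for a, b, e in truth.loops]
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return new


# ---------------------------------------------------------------------------
# Truth serialization (plain-text key/value + BED-like sections)
# ---------------------------------------------------------------------------

def save_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("# hictopo synthetic truth v1\n")
        for key in ("resolution", "alpha", "tad_boost", "plaid_strength",
                    "depth", "trans_depth", "seed", "bb_attenuation",
                    "bb_min_dist", "insulation_range"):
            val = getattr(truth, key)
            val = int(val) if float(val).is_integer() else float(val)
            fh.write(f"{key}\t{val!r}\n")
        fh.write("[chromosomes]\n")
        for c, s in truth.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
        fh.write("[boundaries]\n")
        for b, p in zip(truth.tad_boundaries, truth.boundary_permeability):
            fh.write(f"{int(b)}\t{float(p)!r}\n")
        fh.write("[compartment_profile]\n")
        for v in truth.compartment_profile:
            fh.write(f"{float(v)!r}\n")
        fh.write("[loops]\n")
        for a, b, e in truth.loops:
            fh.write(f"{int(a)}\t{int(b)}\t{float(e)!r}\n")


def load_truth(path) -> SyntheticTruth:
    scalars: dict[str, str] = {}
    sections: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
            elif current is None:
                key, val = line.split("\t")
                scalars[key] = val
            else:
                sections[current].append(line.split("\t"))
    bounds = sections.get("boundaries", [])
    return SyntheticTruth(
        chrom_sizes={c: int(s) for c, s in sections["chromosomes"]},
        resolution=int(scalars["resolution"]),
        alpha=float(scalars["alpha"]),
        tad_boundaries=np.array([int(r[0]) for r in bounds], dtype=np.int64),
        tad_boost=float(scalars["tad_boost"]),
        boundary_permeability=np.array([float(r[1]) for r in bounds]),
        compartment_profile=np.array([float(r[0]) for r in sections["compartment_profile"]]),
        plaid_strength=float(scalars["plaid_strength"]),
        loops=[(int(a), int(b), float(e)) for a, b, e in sections.get("loops", [])],
        depth=float(scalars["depth"]),
        trans_depth=float(scalars["trans_depth"]),
        seed=int(scalars["seed"]),
        bb_attenuation=float(scalars["bb_attenuation"]),
        bb_min_dist=int(float(scalars.get("bb_min_dist", 2_000_000))),
        insulation_range=int(float(scalars.get("insulation_range", 1_200_000))),
    )
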
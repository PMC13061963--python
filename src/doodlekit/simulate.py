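"""Synthetic data with the statistical structure of untemplated synthesis studies.

Three generators emulate the three raw-data modalities so that every
analysis stage can be exercised, with ground truth, without any download:

* **read pools** — mixtures of tandem-repeat reads (GT, AT, AATT, CTATAG,
  GTATATAC, poly-A, A^4T^4, ...) and random reads, with lengths drawn from a
  bimodal log-normal mixture (modes near 80 and 400 nt, as seen for Taq at
  65 C) or an exponential decay (Vent-like), per-base Phred qualities from a
  clipped normal around a target median (~Q13), and substitution/indel
  errors. Sequencing artifacts (terminal adapters/barcodes, concatemers
  joined by an internal adapter) are layered on separately.
* **fluorescence curves** — two-phase piecewise-linear synthesis kinetics:
  a slow phase, a breakpoint near 30 min with a 3-3.5x rate increase, a
  smooth rate decay to zero at the stop time (~180 min), then a plateau,
  plus additive Gaussian noise. Values are computed from the analytic
  integral so noiseless slopes are exact.
* **AFM height maps** — per-row cubic background plus ridges of fixed
  height along molecule polylines (trunks with optional branches) plus
  Gaussian height noise.

Every generated object carries the ground truth needed to score the
downstream module (true class/motif per read, artifact flags, true phase
rates and breakpoint, true trunk/branch lengths). One integer seed drives
each generator through ``numpy.random.SeedSequence`` sub-spawning, so equal
seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .afm import DEFAULT_PIXEL_NM, HeightMap
from .kinetics import KineticsCurve
from .reads import AdapterSet, Read, ReadPool

__all__ = [
    "PoolComponent",
    "LengthModel",
    "PoolSpec",
    "KineticsSpec",
    "MoleculeLayout",
    "AfmLayout",
    "DEFAULT_ADAPTER",
    "simulate_pool",
    "add_sequencing_artifacts",
    "simulate_kinetics_curve",
    "simulate_afm_height_map",
    "random_afm_layout",
    "taq65_pool_spec",
    "vent65_pool_spec",
]

# Oxford Nanopore ligation adapter (top strand), used as the default
# terminal/internal adapter in simulated libraries.
DEFAULT_ADAPTER = "AATGTACTTCGTTCAGTTACGTATTGCT"
DEFAULT_BARCODE = "CACAAAGACACCGACAACTTTCTT"


@dataclass(frozen=True)
class PoolComponent:
    """One mixture component: a tandem motif, "RANDOM", or "POLY-A".

    ``fixed_copies`` pins the tandem copy number; when None the copy number
    is derived from the drawn read length (copies ~ length / |motif|).
    """

    motif: str
    weight: float
    fixed_copies: Optional[int] = None

    def __post_init__(self) -> None:
        if self.motif not in ("RANDOM", "POLY-A") and (
            not self.motif or set(self.motif.upper()) - set("ACGT")
        ):
            raise ValueError(f"invalid component motif {self.motif!r}")
        if self.weight < 0:
            raise ValueError("component weight must be >= 0")


@dataclass(frozen=True)
class LengthModel:
    """Read-length distribution: log-normal mixture or exponential decay.

    ``modes`` lists (mode_nt, sigma, weight) log-normal components; the
    default two-mode model reproduces the bimodal 80/400 nt distribution of
    Taq pools at 65 C. ``kind="exponential"`` draws min_length + Exp(mean)
    instead (Vent-like single peak with a long decay).
    """

    kind: str = "lognormal_mixture"
    modes: tuple[tuple[float, float, float], ...] = ((80.0, 0.35, 0.6), (400.0, 0.35, 0.4))
    exp_mean: float = 120.0
    min_length: int = 20

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "exponential":
            lengths = self.min_length + rng.exponential(self.exp_mean, size=n)
        elif self.kind == "lognormal_mixture":
            weights = np.array([m[2] for m in self.modes], dtype=float)
            weights = weights / weights.sum()
            comp = rng.choice(len(self.modes), size=n, p=weights)
            lengths = np.empty(n)
            for i, (mode, sigma, _) in enumerate(self.modes):
                k = int(np.sum(comp == i))
                # mode of lognormal(mu, sigma) is exp(mu - sigma^2)
                mu = math.log(mode) + sigma**2
                lengths[comp == i] = rng.lognormal(mu, sigma, size=k)
        else:
            raise ValueError(f"unknown length model kind {self.kind!r}")
        return np.maximum(self.min_length, np.round(lengths)).astype(np.int64)


@dataclass(frozen=True)
class PoolSpec:
    components: tuple[PoolComponent, ...]
    length_model: LengthModel = field(default_factory=LengthModel)
    per_base_substitution_rate: Optional[float] = None  # None -> derive from Q
    per_base_indel_rate: float = 0.0
    n_reads: int = 1000
    target_median_q: float = 13.0
    q_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("PoolSpec needs at least one component")
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {total}")
        for rate in (self.per_base_substitution_rate, self.per_base_indel_rate):
            if rate is not None and not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def taq65_pool_spec(n_reads: int = 2000, seed: int = 0, **kw) -> PoolSpec:
    """Preset resembling a Taq 65 C pool: GT-dominated short reads, AT-rich
    long reads, a little poly-A, the rest random; bimodal 80/400 nt lengths."""
    return PoolSpec(
        components=(
            PoolComponent("GT", 0.45),
            PoolComponent("AT", 0.25),
            PoolComponent("POLY-A", 0.05),
            PoolComponent("RANDOM", 0.25),
        ),
        n_reads=n_reads,
        seed=seed,
        **kw,
    )


def vent65_pool_spec(n_reads: int = 2000, seed: int = 0, **kw) -> PoolSpec:
    """Preset resembling a Vent 65 C pool: single ~80 nt peak with an
    exponential-type length decay; GT/AATT repeats plus random reads."""
    return PoolSpec(
        components=(
            PoolComponent("GT", 0.5),
            PoolComponent("AATT", 0.2),
            PoolComponent("RANDOM", 0.3),
        ),
        length_model=LengthModel(kind="exponential", exp_mean=80.0, min_length=40),
        n_reads=n_reads,
        seed=seed,
        **kw,
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(
    seq: np.ndarray,
    quals: np.ndarray,
    rng: np.random.Generator,
    sub_rate: Optional[float],
    indel_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Substitutions (flat rate, or per-base 10^(-Q/10)), then uniform indels."""
    n = seq.size
    p_sub = np.full(n, sub_rate) if sub_rate is not None else 10.0 ** (-quals / 10.0)
    hit = rng.random(n) < p_sub
    if hit.any():
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(_BASES, seq[hit])  # seq bases are in sorted ACGT order
        seq = seq.copy()
        seq[hit] = _BASES[(idx + shifts) % 4]
    if indel_rate > 0 and n > 0:
        out_s, out_q = [], []
        events = rng.random(n) < indel_rate
        is_ins = rng.random(n) < 0.5
        ins_base = _BASES[rng.integers(0, 4, size=n)]
        for i in range(n):
            if events[i]:
                if is_ins[i]:
                    out_s.append(ins_base[i])
                    out_q.append(quals[i])
                    out_s.append(seq[i])
                    out_q.append(quals[i])
                # deletion: drop the base
            else:
                out_s.append(seq[i])
                out_q.append(quals[i])
        seq = np.array(out_s, dtype=np.uint8)
        quals = np.array(out_q, dtype=np.int64)
    return seq, quals


def _draw_quals(rng: np.random.Generator, n: int, median_q: float, sd: float) -> np.ndarray:
    return np.clip(np.round(rng.normal(median_q, sd, size=n)), 2, 41).astype(np.int64)


def simulate_pool(spec: PoolSpec) -> ReadPool:
    """Generate ``spec.n_reads`` reads, each carrying its ground-truth class.

    Repeat reads are tandem copies of the motif starting at a random phase;
    copy number comes from the drawn length unless the component pins it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    weights = np.array([c.weight for c in spec.components])
    comp_idx = rng.choice(len(spec.components), size=spec.n_reads, p=weights)
    lengths = spec.length_model.sample(rng, spec.n_reads)
    reads: list[Read] = []
    for i in range(spec.n_reads):
        comp = spec.components[comp_idx[i]]
        L = int(lengths[i])
        if comp.motif == "RANDOM":
            seq = _BASES[rng.integers(0, 4, size=L)]
            true_class, true_motif = "RANDOM", ""
        elif comp.motif == "POLY-A":
            seq = np.full(L, ord("A"), dtype=np.uint8)
            true_class, true_motif = "POLY-A", "A"
        else:
            motif = comp.motif.upper()
            copies = comp.fixed_copies if comp.fixed_copies is not None else max(
                1, round(L / len(motif))
            )
            phase = int(rng.integers(0, len(motif))) if comp.fixed_copies is None else 0
            s = (motif * (copies + 1))[phase : phase + copies * len(motif)]
            seq = np.frombuffer(s.encode(), dtype=np.uint8)
            true_class, true_motif = motif, motif
        quals = _draw_quals(rng, seq.size, spec.target_median_q, spec.q_sd)
        seq, quals = _apply_errors(
            seq, quals, rng, spec.per_base_substitution_rate, spec.per_base_indel_rate
        )
        reads.append(
            Read(
                f"sim_{i:06d}",
                seq.tobytes().decode(),
                quals,
                meta={"true_class": true_class, "true_motif": true_motif},
            )
        )
    return ReadPool(reads)


def add_sequencing_artifacts(
    pool: ReadPool,
    adapters: AdapterSet | None = None,
    concatemer_rate: float = 0.0,
    seed: int = 0,
    barcode: str | None = DEFAULT_BARCODE,
) -> ReadPool:
    """Attach terminal adapter(+barcode) to every read; make some concatemers.

    A fraction ``concatemer_rate`` of reads is joined with a random partner
    read through an internal copy of the adapter before the terminal
    adapters go on. Ground-truth flags (``has_adapters_truth``,
    ``is_concatemer_truth``) are stored in each read's meta.
    """
    if not (0 <= concatemer_rate <= 1):
        raise ValueError("concatemer_rate must be in [0, 1]")
    adapters = adapters or AdapterSet((DEFAULT_ADAPTER,))
    adapter = adapters.adapters[0]
    prefix = adapter + (barcode or "")
    suffix = (barcode or "") + adapter
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(pool)
    make_concat = rng.random(n) < concatemer_rate
    partners = rng.integers(0, n, size=n)
    out: list[Read] = []
    for i, r in enumerate(pool):
        seq, quals = r.sequence, r.qualities
        meta = dict(r.meta)
        if make_concat[i] and n > 1:
            p = pool[int(partners[i]) if partners[i] != i else (i + 1) % n]
            seq = seq + adapter + p.sequence
            quals = np.concatenate(
                [quals, _draw_quals(rng, len(adapter), 13.0, 3.0), p.qualities]
            )
            meta["is_concatemer_truth"] = True
        else:
            meta["is_concatemer_truth"] = False
        seq = prefix + seq + suffix
        quals = np.concatenate(
            [
                _draw_quals(rng, len(prefix), 13.0, 3.0),
                quals,
                _draw_quals(rng, len(suffix), 13.0, 3.0),
            ]
        )
        meta["has_adapters_truth"] = True
        out.append(Read(r.id, seq, quals, flags=set(r.flags), meta=meta))
    return ReadPool(out)


@dataclass(frozen=True)
class KineticsSpec:
    """Ground truth for a simulated two-phase synthesis curve.

    Defaults mirror the observed regime: breakpoint at 30 min, a 3.25x rate
    increase, linearity until ~120 min, synthesis stopping at 180 min, 5-min
    sampling for 16 h.
    """

    breakpoint_min: float = 30.0
    slow_rate: float = 1.0
    fast_rate: float = 3.25
    saturation_start_min: float = 120.0
    stop_min: float = 180.0
    noise_sd: float = 0.0  # fraction of the curve maximum
    sampling_interval_min: float = 5.0
    duration_min: float = 960.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.breakpoint_min < self.saturation_start_min < self.stop_min <= self.duration_min):
            raise ValueError("need 0 < breakpoint < saturation_start < stop <= duration")
        if not (self.fast_rate > self.slow_rate > 0):
            raise ValueError("need fast_rate > slow_rate > 0")

    def noiseless_value(self, t: np.ndarray) -> np.ndarray:
        """Analytic integral of the piecewise rate; exact linear slopes."""
        t = np.asarray(t, dtype=float)
        b, ss, stop = self.breakpoint_min, self.saturation_start_min, self.stop_min
        T = stop - ss
        y_b = self.slow_rate * b
        y_ss = y_b + self.fast_rate * (ss - b)

        def decay_integral(u):  # integral of fast*0.5*(1+cos(pi u/T)) from 0 to u
            return self.fast_rate * 0.5 * (u + T / math.pi * np.sin(math.pi * u / T))

        y = np.where(
            t <= b,
            self.slow_rate * t,
            np.where(
                t <= ss,
                y_b + self.fast_rate * (t - b),
                y_ss + decay_integral(np.clip(t - ss, 0, T)),
            ),
        )
        return y


def simulate_kinetics_curve(spec: KineticsSpec) -> KineticsCurve:
    """Sample the analytic two-phase curve on a uniform grid, with noise.

    The noiseless template is monotone non-decreasing by construction (the
    rate is everywhere >= 0); a violation indicates an internal error.
    """
    t = np.arange(0.0, spec.duration_min + 1e-9, spec.sampling_interval_min)
    y = spec.noiseless_value(t)
    if np.any(np.diff(y) < -1e-9):
        raise AssertionError("internal error: noiseless kinetics template not monotone")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        y = y + rng.normal(0.0, spec.noise_sd * y.max(), size=y.size)
    rox = np.full_like(t, 1000.0)
    return KineticsCurve(t, y, rox)


@dataclass(frozen=True)
class MoleculeLayout:
    """One molecule as polylines in nm: a trunk and branches off it.

    Each branch polyline starts at its attachment point on the trunk. Points
    are (row_nm, col_nm).
    """

    trunk: tuple[tuple[float, float], ...]
    branches: tuple[tuple[tuple[float, float], ...], ...] = ()

    @staticmethod
    def _polyline_length(points) -> float:
        pts = np.asarray(points, dtype=float)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T))) if len(pts) > 1 else 0.0

    @property
    def trunk_length_nm(self) -> float:
        return self._polyline_length(self.trunk)

    @property
    def branch_lengths_nm(self) -> tuple[float, ...]:
        return tuple(self._polyline_length(b) for b in self.branches)


@dataclass(frozen=True)
class AfmLayout:
    shape_px: tuple[int, int] = (512, 512)
    molecules: tuple[MoleculeLayout, ...] = ()
    pixel_nm: float = DEFAULT_PIXEL_NM
    background_poly_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    background_row_gradient: float = 0.0  # scales the cubic linearly with row index
    noise_sd_nm: float = 0.0
    strand_height_nm: float = 2.0
    ridge_halfwidth_px: int = 1

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        max_r = (self.shape_px[0] - 1) * self.pixel_nm
        max_c = (self.shape_px[1] - 1) * self.pixel_nm
        for mol in self.molecules:
            for path in (mol.trunk, *mol.branches):
                for r, c in path:
                    if not (0 <= r <= max_r and 0 <= c <= max_c):
                        raise ValueError(f"path point ({r}, {c}) nm outside image bounds")


def simulate_afm_height_map(layout: AfmLayout, seed: int = 0) -> HeightMap:
    """Per-row cubic background + molecule ridges + Gaussian height noise."""
    from skimage.draw import line as draw_line
    from skimage.morphology import dilation, disk

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = layout.shape_px
    x = np.arange(cols, dtype=float)
    c0, c1, c2, c3 = layout.background_poly_coeffs
    base_row = c0 + c1 * x + c2 * x**2 + c3 * x**3
    row_scale = 1.0 + layout.background_row_gradient * np.arange(rows, dtype=float)
    heights = row_scale[:, None] * base_row[None, :]

    ridge = np.zeros((rows, cols), dtype=bool)
    for mol in layout.molecules:
        for path in (mol.trunk, *mol.branches):
            pts = np.asarray(path, dtype=float) / layout.pixel_nm
            pix = np.round(pts).astype(int)
            for (r0, cc0), (r1, cc1) in zip(pix, pix[1:]):
                rr, cc = draw_line(r0, cc0, r1, cc1)
                ridge[rr, cc] = True
    if layout.ridge_halfwidth_px > 0 and ridge.any():
        ridge = dilation(ridge, disk(layout.ridge_halfwidth_px))
    heights = heights + layout.strand_height_nm * ridge
    if layout.noise_sd_nm > 0:
        heights = heights + rng.normal(0.0, layout.noise_sd_nm, size=heights.shape)
    return HeightMap(heights, layout.pixel_nm)


def random_afm_layout(
    seed: int,
    shape_px: tuple[int, int] = (360, 360),
    n_molecules: int = 4,
    branch_prob: float = 0.25,
    noise_sd_nm: float = 0.1,
    pixel_nm: float = DEFAULT_PIXEL_NM,
) -> AfmLayout:
    """Random well-separated straight-trunk molecules for recovery tests.

    Molecules are placed one per grid cell so masks never merge. Each trunk
    is a straight segment; with probability ``branch_prob`` one straight
    branch leaves an interior trunk point at a transversal angle.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = shape_px
    grid = int(math.ceil(math.sqrt(n_molecules)))
    cell_r, cell_c = rows // grid, cols // grid
    margin_px = 12
    molecules: list[MoleculeLayout] = []
    cells = [(i, j) for i in range(grid) for j in range(grid)]
    rng.shuffle(cells)
    for (gi, gj) in cells[:n_molecules]:
        r_lo, c_lo = gi * cell_r + margin_px, gj * cell_c + margin_px
        r_hi, c_hi = (gi + 1) * cell_r - margin_px, (gj + 1) * cell_c - margin_px
        span = min(r_hi - r_lo, c_hi - c_lo)
        if span < 40:
            continue
        center = np.array(
            [rng.uniform(r_lo + span * 0.3, r_hi - span * 0.3),
             rng.uniform(c_lo + span * 0.3, c_hi - span * 0.3)]
        )
        angle = rng.uniform(0, math.pi)
        half = rng.uniform(span * 0.22, span * 0.28)
        d = np.array([math.sin(angle), math.cos(angle)])
        p0, p1 = center - half * d, center + half * d
        branches: list[tuple[tuple[float, float], ...]] = []
        if rng.random() < branch_prob:
            frac = rng.uniform(0.42, 0.58)
            attach = p0 + frac * (p1 - p0)
            # keep the branch shorter than both trunk arms, otherwise the
            # maximum-path trunk definition legitimately routes through it
            min_arm = 2 * half * min(frac, 1.0 - frac)
            b_angle = angle + rng.choice([-1, 1]) * rng.uniform(math.pi / 3, math.pi / 2)
            b_len = rng.uniform(0.7, 0.9) * min_arm
            b_end = attach + b_len * np.array([math.sin(b_angle), math.cos(b_angle)])
            b_end = np.clip(b_end, [r_lo, c_lo], [r_hi, c_hi])
            branches.append((tuple(attach * pixel_nm), tuple(b_end * pixel_nm)))
        molecules.append(
            MoleculeLayout(
                trunk=(tuple(p0 * pixel_nm), tuple(p1 * pixel_nm)),
                branches=tuple(branches),
            )
        )
    return AfmLayout(
        shape_px=shape_px,
        molecules=tuple(molecules),
        pixel_nm=pixel_nm,
        noise_sd_nm=noise_sd_nm,
    )
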
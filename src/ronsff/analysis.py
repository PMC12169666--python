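"""Structural analysis of solution trajectories.

Implements the post-processing used to characterize ionic hydration and
pairing: radial distribution functions g(r) under the minimum-image
convention in orthorhombic boxes, first-shell distance cutoffs taken at
the minimum after the first RDF peak, and the degree of ionization (the
fraction of ions with no counterion inside the first-shell cutoff).
A deterministic fixture generator produces frames with known structure
so every analysis is testable without molecular-dynamics input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "FrameSet",
    "RDFCurve",
    "compute_rdf",
    "first_shell_cutoff",
    "degree_of_ionization",
    "generate_fixture_frames",
]


@dataclass
class Frame:
    positions: np.ndarray          # (N, 3), nm
    box: np.ndarray                # (3,), orthorhombic edge lengths, nm
    labels: np.ndarray             # (N,) per-particle group labels

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels/positions length mismatch")

    def select(self, label: str) -> np.ndarray:
        return self.positions[self.labels == label]


@dataclass
class FrameSet:
    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a FrameSet needs at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class RDFCurve:
    r: np.ndarray                  # bin centers, nm
    g: np.ndarray                  # dimensionless
    bin_width: float
    n_frames: int
    counts: np.ndarray = field(default=None)  # raw pair counts per bin

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)


def minimum_image_distances(a: np.ndarray, b: np.ndarray,
                            box: np.ndarray) -> np.ndarray:
    """All pairwise distances between position sets a and b under the
    minimum-image convention; for a is b, self-pairs are dropped."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    dist = np.sqrt((d ** 2).sum(axis=-1))
    if a is b:
        iu = np.triu_indices(len(a), k=1)
        return dist[iu]
    return dist.ravel()


def compute_rdf(
    frames: FrameSet,
    group_a: str,
    group_b: str,
    bin_width: float = 0.002,
    r_max: float | None = None,
) -> RDFCurve:
    """Pair-distance histogram normalized by the ideal-gas expectation."""
    box0 = frames.frames[0].box
    limit = float(box0.min()) / 2.0
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-12:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge ({limit})"
        )
    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    counts = np.zeros(nbins)
    norm = np.zeros(nbins)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for fr in frames:
        pa = fr.select(group_a)
        pb = pa if group_b == group_a else fr.select(group_b)
        if len(pa) == 0 or len(pb) == 0:
            raise ValueError("empty selection for RDF")
        dist = minimum_image_distances(pa, pa if group_b == group_a else pb,
                                       fr.box)
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        vol = float(np.prod(fr.box))
        if group_a == group_b:
            npairs = len(pa) * (len(pa) - 1) / 2.0
        else:
            npairs = len(pa) * len(pb)
        norm += npairs * shell / vol
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFCurve(r=centers, g=g, bin_width=bin_width,
                    n_frames=len(frames), counts=counts)


def first_shell_cutoff(rdf: RDFCurve, smooth_bins: int = 3) -> float:
    """Position of the first local minimum after the first RDF peak.

    A fixed-width moving average (default 3 bins) is applied before the
    search; raises if the curve has no peak-then-minimum structure.
    """
    g = rdf.g
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        g = np.convolve(g, kernel, mode="same")
    # first peak: global maximum of the smoothed curve
    ipk = int(np.argmax(g))
    if ipk == 0 or ipk >= len(g) - 2 or g[ipk] <= 0:
        raise ValueError("RDF has no resolvable first peak")
    seg = g[ipk:]
    for n in range(1, len(seg) - 1):
        if seg[n] <= seg[n - 1] and seg[n] < seg[n + 1]:
            return float(rdf.r[ipk + n])
    raise ValueError("no local minimum found after the first RDF peak")


def degree_of_ionization(
    frames: FrameSet,
    ion_label: str,
    counterion_label: str,
    cutoff: float,
) -> float:
    """Frame-averaged fraction of ions with zero counterions within cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    fracs = []
    for fr in frames:
        ions = fr.select(ion_label)
        counter = fr.select(counterion_label)
        if len(ions) == 0 or len(counter) == 0:
            raise ValueError("empty ion or counterion selection")
        d = ions[:, None, :] - counter[None, :, :]
        d -= fr.box * np.round(d / fr.box)
        dist = np.sqrt((d ** 2).sum(axis=-1))
        free = np.all(dist > cutoff, axis=1)
        fracs.append(free.mean())
    return float(np.mean(fracs))


def generate_fixture_frames(
    kind: str,
    seed: int = 0,
    n_particles: int = 1000,
    box: float = 5.0,
    n_frames: int = 1,
    paired_fraction: float = 0.5,
    n_ions: int = 64,
    contact: float = 0.25,
    lattice_n: int = 5,
    label: str = "A",
) -> FrameSet:
    """Deterministic synthetic frames with known structure.

    ``ideal_gas``: uniformly random particles (label ``A``).
    ``paired_fraction``: ``n_ions`` ions (label ``ION``) of which a
    fraction ``paired_fraction`` has a counterion (label ``CION``)
    placed at contact distance; the remaining counterions are placed
    far from every ion.
    ``lattice``: a simple-cubic lattice of spacing box/lattice_n.
    """
    rng = np.random.default_rng(seed)
    box_vec = np.array([box, box, box], dtype=float)
    frames: list[Frame] = []
    if kind == "ideal_gas":
        for _ in range(n_frames):
            pos = rng.random((n_particles, 3)) * box
            frames.append(Frame(pos, box_vec, np.array([label] * n_particles)))
    elif kind == "paired_fraction":
        n_paired = int(round(paired_fraction * n_ions))
        if not 0 <= n_paired <= n_ions:
            raise ValueError("infeasible paired fraction")
        # ions on a coarse grid so that no two sites approach the cutoff
        grid = np.ceil(n_ions ** (1 / 3))
        spacing = box / grid
        if spacing < 4 * contact:
            raise ValueError("infeasible packing: too many ions for the box")
        sites = []
        for ix in range(int(grid)):
            for iy in range(int(grid)):
                for iz in range(int(grid)):
                    sites.append((ix, iy, iz))
        sites = (np.array(sites[:n_ions], dtype=float) + 0.25) * spacing
        for _ in range(n_frames):
            counter = []
            for n in range(n_ions):
                if n < n_paired:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    counter.append(sites[n] + 0.8 * contact * direction)
                else:
                    counter.append(sites[n] + spacing / 2.0)
            pos = np.vstack([sites, np.array(counter)])
            labels = np.array(["ION"] * n_ions + ["CION"] * n_ions)
            frames.append(Frame(pos % box, box_vec, labels))
    elif kind == "lattice":
        spacing = box / lattice_n
        pts = [(ix, iy, iz) for ix in range(lattice_n)
               for iy in range(lattice_n) for iz in range(lattice_n)]
        pos = np.array(pts, dtype=float) * spacing
        for _ in range(n_frames):
            frames.append(Frame(pos.copy(), box_vec,
                                np.array([label] * len(pos))))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return FrameSet(frames)
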
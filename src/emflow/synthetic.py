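"""Desk-scale synthetic cryo-EM data and the image primitives used on it.

The generator emulates the shape of a single-particle acquisition at toy
size: multi-frame movies containing Gaussian "particles" planted at
known positions, a rigid per-frame drift, and white Gaussian noise.
A ground-truth ledger (a STAR file) accompanies every movie so that
picking and bookkeeping can be scored exactly.  The synthetic pixel
size is taken as 2 Å/px, so a ribosome-sized particle of 270 Å diameter
corresponds to a 135 px blob at full scale and to the 27 px default of
the small fixtures here.

Also implemented here are the desk-scale stage primitives: integer-shift
motion correction by cross-correlation, Gaussian-template auto-picking
via locally normalised cross-correlation, windowed particle extraction
with block-mean downscaling, and a nearest-mean 2D classifier that
writes per-iteration optimiser checkpoints.  These create real files
with real arithmetic, but make no claim to physical realism: there is
no CTF, no dose damage, no alignment beyond whole-pixel shifts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import match_template, peak_local_max

import gemmi

from .errors import ValidationError
from .star import StarBlock, StarDocument, read_star, write_star

PIXEL_SIZE_A = 2.0  # Å per pixel at "full scale"


# -- MRC I/O (mode 2 float, via gemmi; byte-deterministic writes) ----------


def write_mrc(path: str | Path, data: np.ndarray) -> None:
    """Write a 2-D image or 3-D stack as a float32 MRC/CCP4 map."""
    arr = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValidationError(f"expected 2-D or 3-D array, got shape {arr.shape}")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> np.ndarray:
    """Read an MRC file back as a float32 array (frames, rows, cols)."""
    m = gemmi.read_ccp4_map(str(path))
    return np.array(m.grid, copy=True, dtype=np.float32)


# -- scene and movie generation -------------------------------------------


@dataclass
class SyntheticScene:
    """A planted field of particles for one movie.

    Coordinates are 0-based (x, y) pixel centres; all must lie at least
    ``particle_diameter/2`` from every image edge.  ``drift`` is applied
    cumulatively: frame k (0-based) is shifted by ``k * drift`` pixels.
    """

    image_size: int = 512
    particle_diameter: int = 27
    coords: list[tuple[int, int]] = field(default_factory=list)
    drift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px per frame
    noise_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        margin = self.particle_diameter / 2
        for x, y in self.coords:
            if not (margin <= x <= self.image_size - 1 - margin
                    and margin <= y <= self.image_size - 1 - margin):
                raise ValidationError(
                    f"coordinate ({x},{y}) closer than {margin} px to an edge")


def gaussian_template(width: int) -> np.ndarray:
    """A unit-peak 2-D Gaussian whose ±2σ support spans *width* pixels."""
    if width < 3:
        raise ValidationError("template width must be >= 3 px")
    size = int(width) | 1  # odd so the peak sits on a pixel
    sigma = width / 4.0
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * sigma**2)).astype(np.float32)


def _render_frame(scene: SyntheticScene, shift: tuple[float, float]) -> np.ndarray:
    n = scene.image_size
    img = np.zeros((n, n), dtype=np.float32)
    tmpl = gaussian_template(scene.particle_diameter)
    half = tmpl.shape[0] // 2
    for x, y in scene.coords:
        cx = int(round(x + shift[0]))
        cy = int(round(y + shift[1]))
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        tr0, tc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(n, r1), min(n, c1)
        if r1 <= r0 or c1 <= c0:
            continue
        img[r0:r1, c0:c1] += tmpl[tr0:tr0 + (r1 - r0), tc0:tc0 + (c1 - c0)]
    return img


def make_movie(scene: SyntheticScene, n_frames: int,
               path: str | Path, ledger_path: str | Path | None = None) -> None:
    """Write an MRC movie stack plus (optionally) its ground-truth ledger.

    Frame k holds the planted blobs shifted by the cumulative drift
    ``k * scene.drift`` with i.i.d. Gaussian noise of ``noise_sigma`` on
    top; everything is reproducible from ``scene.seed``.
    """
    scene.validate()
    rng = np.random.default_rng(scene.seed)
    frames = []
    for k in range(n_frames):
        shift = (scene.drift[0] * k, scene.drift[1] * k)
        f = _render_frame(scene, shift)
        if scene.noise_sigma > 0:
            f = f + rng.normal(0.0, scene.noise_sigma, f.shape).astype(np.float32)
        frames.append(f.astype(np.float32))
    write_mrc(path, np.stack(frames))
    if ledger_path is not None:
        doc = StarDocument()
        doc.add("scene", StarBlock.from_pairs({
            "emflowImageSize": str(scene.image_size),
            "emflowParticleDiameter": str(scene.particle_diameter),
            "emflowDriftX": repr(scene.drift[0]),
            "emflowDriftY": repr(scene.drift[1]),
            "emflowNoiseSigma": repr(scene.noise_sigma),
            "emflowSeed": str(scene.seed),
            "emflowNFrames": str(n_frames),
        }))
        doc.add("ground_truth", StarBlock.from_table(
            ["emflowCoordinateX", "emflowCoordinateY"],
            [[str(x), str(y)] for x, y in scene.coords]))
        write_star(doc, ledger_path)


def read_ledger(path: str | Path) -> list[tuple[int, int]]:
    doc = read_star(path)
    return [(int(x), int(y)) for x, y in doc["ground_truth"].rows]


def random_scene(seed: int, image_size: int = 512, n_particles: int = 6,
                 particle_diameter: int = 27,
                 min_separation: float | None = None,
                 drift: tuple[float, float] = (1.0, 0.0),
                 noise_sigma: float = 0.1) -> SyntheticScene:
    """Draw a scene with well-separated particles (default ≥ 2× diameter)."""
    rng = np.random.default_rng(seed)
    sep = min_separation if min_separation is not None else 2.0 * particle_diameter
    margin = int(np.ceil(particle_diameter / 2)) + 2
    coords: list[tuple[int, int]] = []
    attempts = 0
    while len(coords) < n_particles:
        attempts += 1
        if attempts > 10000:
            raise ValidationError(
                f"cannot place {n_particles} particles at separation {sep} "
                f"in a {image_size} px image")
        x = int(rng.integers(margin, image_size - margin))
        y = int(rng.integers(margin, image_size - margin))
        if all((x - u) ** 2 + (y - v) ** 2 >= sep**2 for u, v in coords):
            coords.append((x, y))
    return SyntheticScene(image_size=image_size,
                          particle_diameter=particle_diameter,
                          coords=coords, drift=drift,
                          noise_sigma=noise_sigma, seed=seed)


# -- acquisition simulation ------------------------------------------------


class AcquisitionSimulator:
    """Emulates a microscope session by timed file copies.

    Movies staged elsewhere are copied into the project's watch
    directory at ``start + i * interval`` on the injected clock; a
    ledger of delivered names supports exactly-once accounting.
    """

    def __init__(self, staged: list[Path], dest_dir: Path, interval: float,
                 clock, start: float | None = None):
        import shutil as _shutil

        self._shutil = _shutil
        self.staged = list(staged)
        self.dest_dir = Path(dest_dir)
        self.interval = float(interval)
        self.clock = clock
        self.start = clock.now() if start is None else start
        self.delivered: list[str] = []

    def due(self, now: float | None = None) -> int:
        now = self.clock.now() if now is None else now
        if self.interval <= 0 or now == float("inf"):
            return len(self.staged)
        return min(len(self.staged), max(0, int((now - self.start) / self.interval) + 1))

    def deliver_due(self, now: float | None = None) -> list[str]:
        """Copy every staged file whose scheduled time has passed."""
        self.dest_dir.mkdir(parents=True, exist_ok=True)
        out = []
        for i in range(len(self.delivered), self.due(now)):
            src = self.staged[i]
            dst = self.dest_dir / src.name
            self._shutil.copyfile(src, dst)
            self.delivered.append(src.name)
            out.append(src.name)
        return out

    def deliver_all(self) -> list[str]:
        return self.deliver_due(now=float("inf"))


# -- stage primitives ------------------------------------------------------


def estimate_shifts(movie: np.ndarray) -> np.ndarray:
    """Integer (dx, dy) shift of each frame relative to frame 0, found by
    maximising the circular cross-correlation computed via FFT."""
    n_frames, h, w = movie.shape
    ref = np.fft.rfft2(movie[0])
    shifts = np.zeros((n_frames, 2), dtype=int)
    for k in range(1, n_frames):
        cc = np.fft.irfft2(ref * np.conj(np.fft.rfft2(movie[k])), s=(h, w))
        peak = np.unravel_index(np.argmax(cc), cc.shape)
        dy = peak[0] if peak[0] <= h // 2 else peak[0] - h
        dx = peak[1] if peak[1] <= w // 2 else peak[1] - w
        # cc peak at (dy,dx) means frame k is frame 0 shifted by (+dx,+dy)... sign:
        shifts[k] = (-dx, -dy)
    return shifts


def motion_correct(movie: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Align all frames to frame 0 by whole-pixel shifts and average.

    Returns (micrograph, per-frame shifts); the estimated shift of frame
    k is the displacement of its content relative to frame 0.
    """
    shifts = estimate_shifts(movie)
    aligned = np.empty_like(movie)
    for k in range(movie.shape[0]):
        aligned[k] = np.roll(movie[k], shift=(-shifts[k][1], -shifts[k][0]),
                             axis=(0, 1))
    return aligned.mean(axis=0).astype(np.float32), shifts


def pseudo_defocus(name: str) -> float:
    """Deterministic placeholder defocus (Å) derived from the item name."""
    return 10000.0 + (zlib.crc32(name.encode()) % 20000)


def gaussian_pick(image: np.ndarray, width: int, height: float,
                  min_distance: int | None = None) -> list[tuple[int, int, float]]:
    """Template-match a unit-peak Gaussian blob against *image*.

    The correlation is the locally normalised cross-correlation (range
    [-1, 1], so the *height* threshold is scale-free).  Local maxima with
    correlation >= height, separated by at least *min_distance* pixels
    (default: half the width), become picks.  Returns (x, y, score)
    tuples sorted by decreasing score, ties broken by position.
    """
    if not 0 < height <= 1:
        raise ValidationError(f"gaussian height must be in (0, 1], got {height}")
    if width > min(image.shape):
        raise ValidationError(
            f"gaussian width {width} exceeds image size {image.shape}")
    tmpl = gaussian_template(width)
    corr = match_template(image.astype(np.float32), tmpl, pad_input=True)
    md = min_distance if min_distance is not None else max(1, width // 2)
    peaks = peak_local_max(corr, min_distance=md, threshold_abs=height,
                           exclude_border=False)
    picks = [(int(c), int(r), float(corr[r, c])) for r, c in peaks]
    picks.sort(key=lambda p: (-p[2], p[1], p[0]))
    return picks


def block_mean_downscale(arr: np.ndarray, factor: int) -> np.ndarray:
    h, w = arr.shape
    if h % factor or w % factor:
        raise ValidationError(f"shape {arr.shape} not divisible by {factor}")
    return arr.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def extract_particles(image: np.ndarray, coords: list[tuple[int, int]],
                      box_size: int, downscale: int = 1
                      ) -> tuple[np.ndarray, list[int], int]:
    """Crop ``box_size``² windows centred on each coordinate and block-mean
    downscale them to ``(box_size/downscale)``² boxes.

    Windows that would cross a micrograph edge are skipped and counted.
    Returns (stack, indices of kept coordinates, number skipped).
    """
    if downscale < 1:
        raise ValidationError("downscale factor must be >= 1")
    if box_size % downscale:
        raise ValidationError(
            f"box size {box_size} not divisible by downscale factor {downscale}")
    h, w = image.shape
    half = box_size // 2
    out_box = box_size // downscale
    kept: list[np.ndarray] = []
    kept_idx: list[int] = []
    skipped = 0
    for i, (x, y) in enumerate(coords):
        r0, c0 = y - half, x - half
        if r0 < 0 or c0 < 0 or r0 + box_size > h or c0 + box_size > w:
            skipped += 1
            continue
        win = image[r0:r0 + box_size, c0:c0 + box_size]
        if downscale > 1:
            win = block_mean_downscale(win, downscale)
        kept.append(win.astype(np.float32))
        kept_idx.append(i)
    stack = (np.stack(kept) if kept
             else np.zeros((0, out_box, out_box), dtype=np.float32))
    return stack, kept_idx, skipped


def classify_2d(particles: np.ndarray, k: int, seed: int, iterations: int,
                job_dir: Path, start_iter: int = 0,
                init_means: np.ndarray | None = None) -> np.ndarray:
    """Nearest-mean 2D classification with per-iteration checkpoints.

    Particles (N, h, w) are iteratively assigned to the closest of *k*
    mean images (Euclidean distance on pixel vectors) and the means are
    re-estimated; an empty class keeps its previous mean.  Every
    iteration writes ``run_it###_classes.mrcs``, ``_model.star``,
    ``_data.star`` and ``_optimiser.star``, so interrupted runs can be
    resumed from the newest checkpoint (pass ``start_iter`` and
    ``init_means``).  Returns the final assignment vector.
    """
    n = particles.shape[0]
    if k < 1:
        raise ValidationError("number of classes must be >= 1")
    if n == 0:
        raise ValidationError("no particles to classify")
    flat = particles.reshape(n, -1).astype(np.float64)
    if init_means is not None:
        means = init_means.reshape(k, -1).astype(np.float64)
    else:
        rng = np.random.default_rng(seed)
        means = flat[rng.choice(n, size=min(k, n), replace=False)]
        if k > n:
            means = np.vstack([means, np.tile(flat.mean(0), (k - n, 1))])
    assign = np.zeros(n, dtype=int)
    job_dir = Path(job_dir)
    job_dir.mkdir(parents=True, exist_ok=True)
    for it in range(start_iter + 1, start_iter + iterations + 1):
        d2 = ((flat[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for j in range(k):
            sel = assign == j
            if sel.any():
                means[j] = flat[sel].mean(axis=0)
        _write_class2d_checkpoint(job_dir, it, k, seed, n,
                                  means.reshape(k, *particles.shape[1:]), assign)
    return assign


def _write_class2d_checkpoint(job_dir: Path, it: int, k: int, seed: int,
                              n: int, means: np.ndarray,
                              assign: np.ndarray) -> None:
    stem = f"run_it{it:03d}"
    write_mrc(job_dir / f"{stem}_classes.mrcs", means.astype(np.float32))
    model = StarDocument()
    model.add("model_classes", StarBlock.from_table(
        ["emflowClassNumber", "emflowClassSize"],
        [[str(j + 1), str(int((assign == j).sum()))] for j in range(k)]))
    write_star(model, job_dir / f"{stem}_model.star")
    data = StarDocument()
    data.add("particles", StarBlock.from_table(
        ["emflowParticleIndex", "emflowClassNumber"],
        [[str(i), str(int(c) + 1)] for i, c in enumerate(assign)]))
    write_star(data, job_dir / f"{stem}_data.star")
    opt = StarDocument()
    opt.add("optimiser", StarBlock.from_pairs({
        "emflowIteration": str(it),
        "emflowNClasses": str(k),
        "emflowNParticles": str(n),
        "emflowSeed": str(seed),
        "emflowClassesFile": f"{stem}_classes.mrcs",
        "emflowModelFile": f"{stem}_model.star",
        "emflowDataFile": f"{stem}_data.star",
    }))
    write_star(opt, job_dir / f"{stem}_optimiser.star")
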
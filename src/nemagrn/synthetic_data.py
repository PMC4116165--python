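"""Synthetic inputs for every pipeline stage.

Real inputs to the workflow are curated in-situ hybridization micrographs and
the expression profiles quantified from them.  This module generates
stand-ins with known ground truth so every downstream stage is testable
without downloads:

* profile templates matching the observed cluster shapes — endodermal
  (central domain, segments 40-60), oral (peaks in segments 30-40 and 60-70),
  border (narrow peaks at the domain edges), and a smooth maternal gradient;
* noisy sampled profiles and a Table-1-like panel of genes across stages;
* rendered embryo images with a known staining profile along the cell layer,
  for round-trip validation of the quantification stage;
* reference data simulated from a known gene circuit, for parameter-recovery
  experiments.

All randomness flows through explicit seeds or generators; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import gene_circuit as gc
from .morphology import Morphology, annulus_morphology
from .quantification import (N_STANDARD_POINTS, StandardizedProfile,
                             decompose_cell_layer)
from skimage.draw import polygon as _raster_polygon

CLUSTER_KINDS = ("endodermal", "oral", "border", "maternal", "zeros")

#: Gaussian-bump layout per cluster kind on the standard 100-segment axis:
#: (centers, standard deviations), in 1-based segment units.
DEFAULT_BUMPS: Mapping[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "endodermal": ((50.0,), (6.0,)),
    "oral": ((35.0, 65.0), (3.0, 3.0)),
    "border": ((40.0, 60.0), (1.5, 1.5)),
    "maternal": ((50.0,), (20.0,)),
    "zeros": ((), ()),
}


class SyntheticDataError(ValueError):
    """Invalid template or rendering request."""


@dataclass(frozen=True)
class ProfileTemplate:
    """Noise-free profile shape built from Gaussian bumps, unit maximum."""

    cluster_kind: str
    n_points: int
    peak_centers: tuple[float, ...]
    peak_widths: tuple[float, ...]
    values: np.ndarray


def make_template(cluster_kind: str, n_points: int = N_STANDARD_POINTS,
                  peak_centers: Sequence[float] | None = None,
                  peak_widths: Sequence[float] | None = None) -> ProfileTemplate:
    """Build a profile template for one cluster kind.

    The template is a sum of Gaussian bumps evaluated at segment centers
    1..n_points and rescaled to unit maximum; ``zeros`` yields the all-zero
    profile.
    """
    if cluster_kind not in CLUSTER_KINDS:
        raise SyntheticDataError(
            f"unknown cluster_kind {cluster_kind!r}; expected one of {CLUSTER_KINDS}")
    if n_points < 10:
        raise SyntheticDataError("templates need n_points >= 10")
    scale = n_points / N_STANDARD_POINTS  # bump layout scales with the axis
    if peak_centers is None:
        centers = tuple(c * scale for c in DEFAULT_BUMPS[cluster_kind][0])
        widths = tuple(w * scale for w in DEFAULT_BUMPS[cluster_kind][1])
    else:
        centers = tuple(float(c) for c in peak_centers)
        widths = tuple(float(w) for w in (peak_widths or ()))
        if len(centers) != len(widths):
            raise SyntheticDataError("peak_centers and peak_widths must match")
        if any(not 1 <= c <= n_points for c in centers):
            raise SyntheticDataError("peak centers must lie within [1, n_points]")
        if any(w <= 0 for w in widths):
            raise SyntheticDataError("peak widths must be positive")
    x = np.arange(1, n_points + 1, dtype=float)
    values = np.zeros(n_points)
    for c, w in zip(centers, widths):
        values += np.exp(-0.5 * ((x - c) / w) ** 2)
    mx = values.max() if len(centers) else 0.0
    if mx > 0:
        values = values / mx
    return ProfileTemplate(cluster_kind, n_points, centers, widths, values)


def sample_profile(template: ProfileTemplate, noise_sd: float,
                   seed: int | np.random.Generator = 0, gene: str = "",
                   stage_hours: float = 0.0) -> StandardizedProfile:
    """Noisy realization of a template: additive Gaussian noise clipped at
    zero, re-normalized to unit maximum (skipped if all-zero)."""
    if noise_sd < 0:
        raise SyntheticDataError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = template.values.copy()
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    mx = values.max()
    if mx > 0:
        values = values / mx
    return StandardizedProfile(gene, stage_hours, values)


# ---------------------------------------------------------------------------
# Synthetic expression panel (a Table-1-like gene collection)
# ---------------------------------------------------------------------------

#: Gene panel mirroring the observed grouping of gut-formation genes:
#: maternal-group genes present from cleavage, endodermal and oral-pole genes
#: appearing at gastrulation, and late genes first seen in the planula.
#: Each entry: (cluster kind, stages in hours at which profiles exist,
#: number of profiles per stage).
DEFAULT_PANEL: Mapping[str, tuple[str, tuple[float, ...], int]] = {
    "Bcat": ("maternal", (5.0, 24.0, 72.0), 3),
    "dsh": ("maternal", (5.0, 24.0, 72.0), 1),
    "tcf": ("oral", (5.0, 24.0, 72.0), 1),
    "otxA": ("endodermal", (24.0, 72.0), 2),
    "otxC": ("endodermal", (24.0, 72.0), 1),
    "snail": ("endodermal", (24.0, 72.0), 4),
    "bra": ("oral", (24.0, 72.0), 2),
    "foxA": ("oral", (24.0, 72.0), 4),
    "otxB": ("oral", (24.0, 72.0), 1),
    "spr": ("oral", (24.0, 72.0), 1),
    "foxC": ("oral", (72.0,), 1),
    "msx": ("oral", (72.0,), 1),
    "twi": ("border", (72.0,), 2),
}


def synthetic_profile_panel(seed: int = 0, noise_sd: float = 0.05,
                            panel: Mapping | None = None) -> list[StandardizedProfile]:
    """Generate a full panel of noisy profiles across genes and stages."""
    rng = np.random.default_rng(seed)
    panel = DEFAULT_PANEL if panel is None else panel
    profiles: list[StandardizedProfile] = []
    for gene, (kind, stages, n_per) in panel.items():
        template = make_template(kind)
        for stage in stages:
            for _ in range(n_per):
                profiles.append(sample_profile(template, noise_sd, rng,
                                               gene=gene, stage_hours=stage))
    return profiles


# ---------------------------------------------------------------------------
# Synthetic embryo images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Specification of a rendered stained-embryo image.

    ``layer_profile`` gives the stain intensity (0..1) along the cell layer
    in path order; its length sets the number of rendered segments.
    """

    canvas: tuple[int, int] = (200, 200)  # (height, width) pixels
    morphology: Morphology = field(default_factory=annulus_morphology)
    layer_profile: np.ndarray = field(
        default_factory=lambda: make_template("endodermal").values)
    channel: str = "R"
    noise_sd: float = 0.0
    background: float = 0.0


def render_embryo_image(spec: SyntheticImageSpec,
                        seed: int | np.random.Generator = 0
                        ) -> tuple[np.ndarray, Morphology]:
    """Render an RGB image with the given staining along the cell layer.

    Pixels between the inner and outer boundary receive the stain intensity
    of their segment in the chosen channel; everything else is background.
    Returns the image (float, clipped to [0, 1]) and the exact morphology
    used, so quantification can be validated round-trip.
    """
    profile = np.asarray(spec.layer_profile, dtype=float).ravel()
    h, w = spec.canvas
    morph = spec.morphology
    all_pts = np.vstack([morph.outer_loop, morph.inner_loop])
    if (all_pts[:, 0].min() < 0 or all_pts[:, 1].min() < 0
            or all_pts[:, 0].max() > w - 1 or all_pts[:, 1].max() > h - 1):
        raise SyntheticDataError("morphology loops must lie inside the canvas")
    decomp = decompose_cell_layer(morph, n_segments=len(profile))
    channel_idx = {"R": 0, "G": 1, "B": 2}.get(spec.channel)
    if channel_idx is None:
        raise SyntheticDataError("stain channel must be R, G or B")
    image = np.full((h, w, 3), float(spec.background))
    for value, quad in zip(profile, decomp.quads):
        rr, cc = _raster_polygon(quad[:, 1], quad[:, 0], shape=(h, w))
        image[rr, cc, channel_idx] = spec.background + value * (1.0 - spec.background)
    if spec.noise_sd > 0:
        rng = (np.random.default_rng(seed)
               if not isinstance(seed, np.random.Generator) else seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0), morph


# ---------------------------------------------------------------------------
# Ground-truth reference data from a known circuit
# ---------------------------------------------------------------------------

def generate_reference_from_circuit(params: gc.GeneCircuitParams,
                                    maternal_profile: np.ndarray,
                                    times: Sequence[float],
                                    noise_sd: float = 0.0,
                                    seed: int | np.random.Generator = 0,
                                    maternal_name: str = "maternal",
                                    rtol: float = 1e-6, atol: float = 1e-9
                                    ) -> gc.ReferenceData:
    """Simulate a known circuit from zero initial conditions and package the
    result as fitting reference data.

    The target profiles get additive Gaussian noise (clipped at zero) and the
    same per-gene-per-time unit-maximum normalization used when scoring fits,
    so a noiseless reference is exactly self-consistent: the generating
    parameters score an objective of zero.
    """
    times = tuple(float(t) for t in times)
    maternal = np.asarray(maternal_profile, dtype=float).ravel()
    init = np.zeros((params.n, maternal.size))
    result = gc.simulate(params, init, maternal, times, rtol=rtol, atol=atol)
    targets = result.concentrations[1:].copy()
    if noise_sd > 0:
        rng = (np.random.default_rng(seed)
               if not isinstance(seed, np.random.Generator) else seed)
        targets = np.maximum(targets + rng.normal(0.0, noise_sd, size=targets.shape), 0.0)
    # normalize per gene per time, leaving identically-zero profiles alone
    for k in range(targets.shape[0]):
        for i in range(targets.shape[1]):
            mx = targets[k, i].max()
            if mx > 0:
                targets[k, i] = targets[k, i] / mx
    if not np.all(np.isfinite(targets)):
        raise SyntheticDataError("circuit simulation produced non-finite reference")
    return gc.ReferenceData(params.gene_names, maternal_name, maternal, init,
                            times[1:], targets)


def demo_gut_circuit(gene_names: Sequence[str] = ("foxA", "snail", "twi")
                     ) -> gc.GeneCircuitParams:
    """A known 3-gene ground-truth circuit used in recovery demonstrations.

    Maternal gradient activates the first two genes; the second represses the
    first (sharpening its domain to the flanks of the central gradient) and
    activates the third, which represses itself.
    """
    T = np.array([[0.0, -4.0, 0.0],
                  [0.0, 0.0, 0.0],
                  [0.0, 4.0, -4.0]])
    m = np.array([4.0, 3.0, 0.0])
    h = np.array([-2.0, -2.0, -2.0])
    lam = np.array([0.2, 0.2, 0.2])
    return gc.GeneCircuitParams(tuple(gene_names), T, m, h, lam)
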
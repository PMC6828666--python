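"""Pocket detection: contour smoothed attractive potential into envelopes.

Pipeline: Lennard-Jones potential on a 1 A grid -> truncation to the
attractive part (-0.8 kcal/mol) -> Gaussian smoothing (lambda = 2.6 A) ->
isovalue contour -> 26-connected components -> per-envelope volume and shape
metrics -> druggability verdict by drug-like volume range and sphericity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import grids
from .grids import ConvolutionSpec, GridMap, GridSpec
from .structure import Structure

#: default contour level (map units, i.e. kcal/mol carrying the pi^(3/2)
#: factor of the unnormalized convolution prefactor).  Calibrated once so
#: that the detected envelope of a hollow spherical cavity reproduces the
#: cavity's geometric volume (4/3 pi r^3) across radii 3-6 A; the
#: truncation threshold propagated through the prefactor
#: (-0.8 * pi^(3/2) ~ -4.5) underestimates cavity volumes by ~40%.
DEFAULT_CONTOUR = -2.5


@dataclass(frozen=True)
class PocketConfig:
    spacing: float = grids.POTENTIAL_SPACING
    padding: float = 6.0
    truncation: float = grids.TRUNCATION_THRESHOLD
    lam: float = grids.POCKET_LAMBDA
    contour: float = DEFAULT_CONTOUR
    min_voxels: int = 10
    volume_range: tuple[float, float] = (150.0, 800.0)
    min_sphericity: float = 0.3


@dataclass
class PocketEnvelope:
    """One connected sub-contour region of the smoothed attractive map."""

    voxels: np.ndarray          # (n, 3) integer node indices
    spec: GridSpec
    contour: float
    volume: float = 0.0         # A^3
    centroid: np.ndarray | None = None
    axis_lengths: np.ndarray | None = None  # principal axes, descending, A
    sphericity: float = 0.0     # min/max principal axis, in (0, 1]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class DruggabilityVerdict:
    druggable: bool
    volume_score: float
    shape_score: float
    reasons: list[str] = field(default_factory=list)

    @property
    def score(self) -> float:
        return self.volume_score * self.shape_score


def find_pockets(structure: Structure, config: PocketConfig | None = None,
                 potential: GridMap | None = None) -> list[PocketEnvelope]:
    """Detect ligand-binding envelopes; sorted by volume, largest first.

    ``potential`` may carry a precomputed P0 map on the matching grid to
    avoid recomputation when scanning many conformers that share a box.
    """
    config = config or PocketConfig()
    if potential is None:
        spec = grids.make_grid(structure, config.spacing, config.padding)
        potential = grids.lj_potential_map(structure, spec)
    truncated = grids.truncate_attractive(potential, config.truncation)
    smoothed = grids.gaussian_convolve(truncated, ConvolutionSpec(lam=config.lam))
    mask = smoothed.values <= config.contour
    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    envelopes: list[PocketEnvelope] = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < config.min_voxels:
            continue
        env = PocketEnvelope(voxels=idx, spec=potential.spec,
                             contour=config.contour)
        envelope_metrics(env)
        envelopes.append(env)
    envelopes.sort(key=lambda e: (-e.volume, tuple(e.voxels[0])))
    return envelopes


def envelope_metrics(envelope: PocketEnvelope) -> PocketEnvelope:
    """Fill volume, centroid, principal-axis lengths and sphericity in place.

    Volume is voxel count times h^3.  Axis lengths derive from the voxel
    coordinate covariance (2 * sqrt(3 * eigenvalue), the half-extent of a
    uniform distribution matched in variance); sphericity is the smallest
    over largest axis, defined as 1.0 for a single voxel.
    """
    if envelope.n_voxels == 0:
        raise ValueError("empty envelope")
    h = envelope.spec.spacing
    coords = (np.asarray(envelope.spec.origin)
              + h * envelope.voxels.astype(float))
    envelope.volume = envelope.n_voxels * h ** 3
    envelope.centroid = coords.mean(axis=0)
    # single-voxel variance h^2/12 per axis models the voxel as a cube
    cov = np.cov(coords.T, bias=True) if envelope.n_voxels > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov) + (h * h / 12.0) * np.eye(3)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    envelope.axis_lengths = 2.0 * np.sqrt(3.0 * np.maximum(eigvals, 0.0))
    envelope.sphericity = float(envelope.axis_lengths[-1]
                                / envelope.axis_lengths[0])
    return envelope


def assess_druggability(envelopes: list[PocketEnvelope],
                        config: PocketConfig | None = None
                        ) -> list[DruggabilityVerdict]:
    """Volume-range and sphericity verdict for each envelope."""
    config = config or PocketConfig()
    v_min, v_max = config.volume_range
    verdicts = []
    for env in envelopes:
        reasons: list[str] = []
        vol_ok = v_min <= env.volume <= v_max
        if env.volume < v_min:
            reasons.append("volume below range")
        elif env.volume > v_max:
            reasons.append("volume above range")
        shape_ok = env.sphericity >= config.min_sphericity
        if not shape_ok:
            reasons.append("sphericity below threshold")
        # triangular volume score peaking mid-range; linear shape score
        mid = 0.5 * (v_min + v_max)
        half = 0.5 * (v_max - v_min)
        volume_score = max(0.0, 1.0 - abs(env.volume - mid) / half) \
            if half > 0 else float(vol_ok)
        shape_score = min(1.0, env.sphericity / config.min_sphericity) \
            if config.min_sphericity > 0 else 1.0
        verdicts.append(DruggabilityVerdict(
            druggable=vol_ok and shape_ok,
            volume_score=volume_score,
            shape_score=shape_score,
            reasons=reasons,
        ))
    return verdicts


def druggability_score(envelopes: list[PocketEnvelope],
                       config: PocketConfig | None = None) -> float:
    """Per-model score: best volume x shape product over envelopes (0 if none)."""
    verdicts = assess_druggability(envelopes, config)
    return max((v.score for v in verdicts), default=0.0)
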
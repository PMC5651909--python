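"""Parametric photophysics model rendering tissue meshes into channel stacks.

A membrane pixel with local sensor density ``rho`` and true FRET efficiency
``E`` produces mean counts

    I_CFP  = rho * Q_D * (1 - E)                      + bg
    I_YFP  = rho * Q_A                                 + bg
    I_FRET = rho * G * E + alpha * rho * Q_D * (1 - E)
                         + beta  * rho * Q_A           + bg

i.e. a sensitized-emission term plus donor bleed-through (``alpha``) and
direct acceptor cross-excitation (``beta``) on an autofluorescent
background.  The model is deliberately semi-quantitative: it guarantees a
strictly monotone map from E to the downstream ratiometric index rather
than a radiometric calibration.  Membrane fluorescence is a ridge along
every junction with a Gaussian cross-profile; optional Poisson noise and
detector clipping at the bit depth emulate acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stack import ChannelStack
from .tissue import GroundTruthTissue, pulsing_mesh_series

__all__ = [
    "PhotophysicsParams",
    "channels_from_density",
    "render_membrane_maps",
    "render_stack",
    "render_calibration_images",
    "generate_pulsing_series",
]


@dataclass(frozen=True)
class PhotophysicsParams:
    """Generator-side photophysics; ``alpha_true``/``beta_true`` are the
    bleed-through and cross-excitation fractions the pipeline must recover."""

    alpha_true: float = 0.10
    beta_true: float = 0.10
    donor_brightness: float = 1200.0  # Q_D, counts per unit density
    gauge: float = 2400.0  # G, sensitized counts per unit density per unit E
    acceptor_brightness: float = 1800.0  # Q_A
    autofluorescence: float = 20.0  # mean background counts per slice
    noise: str = "poisson"
    bit_depth: int = 16
    membrane_width: float = 3.0  # px
    z_slices: int = 3
    slice_attenuation: float = 0.5  # per out-of-focus slice
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_true < 1 and 0 <= self.beta_true < 1):
            raise ValueError("alpha_true, beta_true must be in [0, 1)")
        if min(self.donor_brightness, self.gauge, self.acceptor_brightness) <= 0:
            raise ValueError("brightnesses must be > 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def analytic_index(self, E: float) -> float:
        """Noise-free FRET index the pipeline should report for true E."""
        se = self.gauge * E
        return se / (self.donor_brightness * (1.0 - E) + se)


def channels_from_density(
    rho, E, phys: PhotophysicsParams, *, donor=True, acceptor=True, sensitized=True
):
    """Mean channel counts (cfp, yfp, fret) for density ``rho`` and true ``E``.

    ``donor``/``acceptor`` switch the fluorophores off to model the
    calibration genotypes; ``sensitized=False`` models co-expressed separate
    molecules (no intramolecular transfer).
    """
    rho = np.asarray(rho, dtype=float)
    E = np.broadcast_to(np.asarray(E, dtype=float), rho.shape)
    bg = phys.autofluorescence
    donor_em = rho * phys.donor_brightness * (1.0 - E) if donor else np.zeros_like(rho)
    if donor and not sensitized:
        donor_em = rho * phys.donor_brightness  # no transfer: no donor quenching
    acc = rho * phys.acceptor_brightness if acceptor else np.zeros_like(rho)
    sens = rho * phys.gauge * E if (donor and acceptor and sensitized) else 0.0
    cfp = donor_em + bg
    yfp = acc + bg
    fret = sens + phys.alpha_true * donor_em + phys.beta_true * acc + bg
    return cfp, yfp, fret


def render_membrane_maps(
    truth: GroundTruthTissue, membrane_width: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize junctions into a density map and a local-E map.

    Density follows a Gaussian cross-profile (sigma = width/3) across each
    junction polyline; where ridges meet, the nearest (highest-profile)
    junction wins, so every membrane pixel carries a single true E.
    """
    h, w = truth.mesh.image_shape
    rho = np.zeros((h, w))
    emap = np.zeros((h, w))
    sigma = membrane_width / 3.0
    reach = membrane_width
    for edge in truth.mesh.edges:
        e_val = truth.edge_efficiency[edge.id]
        pl = edge.polyline
        r0 = max(int(np.floor(pl[:, 0].min() - reach - 1)), 0)
        r1 = min(int(np.ceil(pl[:, 0].max() + reach + 1)), h - 1)
        c0 = max(int(np.floor(pl[:, 1].min() - reach - 1)), 0)
        c1 = min(int(np.ceil(pl[:, 1].max() + reach + 1)), w - 1)
        if r1 < r0 or c1 < c0:
            continue
        rr, cc = np.meshgrid(
            np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
        )
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        d2 = np.full(pts.shape[0], np.inf)
        for a, b in zip(pl[:-1], pl[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom < 1e-12:
                dd = np.sum((pts - a) ** 2, axis=1)
            else:
                tt = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
                proj = a + tt[:, None] * ab
                dd = np.sum((pts - proj) ** 2, axis=1)
            d2 = np.minimum(d2, dd)
        prof = np.exp(-d2 / (2.0 * sigma**2))
        prof[d2 > reach**2] = 0.0
        prof2 = prof.reshape(rr.shape)
        sub_rho = rho[r0 : r1 + 1, c0 : c1 + 1]
        sub_e = emap[r0 : r1 + 1, c0 : c1 + 1]
        take = prof2 > sub_rho
        sub_rho[take] = prof2[take]
        sub_e[take] = e_val
    return rho, emap


def _stack_slices(mean_img: np.ndarray, phys: PhotophysicsParams) -> np.ndarray:
    """Replicate a focal-plane mean image into attenuated z-slices."""
    nz = phys.z_slices
    focal = nz // 2
    bg = phys.autofluorescence
    slices = []
    for s in range(nz):
        att = phys.slice_attenuation ** abs(s - focal)
        slices.append((mean_img - bg) * att + bg)
    return np.stack(slices)


def _acquire(mean_imgs, phys: PhotophysicsParams, rng) -> list[np.ndarray]:
    """Apply z-stacking, Poisson noise and detector clipping; count clips."""
    out = []
    clipped = 0
    sat = 2**phys.bit_depth - 1
    for img in mean_imgs:
        stack = _stack_slices(img, phys)
        if phys.noise == "poisson":
            stack = rng.poisson(stack).astype(float)
        clipped += int(np.sum(stack > sat))
        out.append(np.minimum(stack, sat))
    return out, clipped


def render_stack(
    truth: GroundTruthTissue, phys: PhotophysicsParams
) -> ChannelStack:
    """Render a three-channel acquisition of a ground-truth tissue."""
    rho, emap = render_membrane_maps(truth, phys.membrane_width)
    cfp, yfp, fret = channels_from_density(rho, emap, phys)
    rng = np.random.default_rng(phys.seed)
    (cfp_s, yfp_s, fret_s), n_clipped = _acquire([cfp, yfp, fret], phys, rng)
    return ChannelStack(
        cfp=cfp_s,
        yfp=yfp_s,
        fret=fret_s,
        bit_depth=phys.bit_depth,
        pixel_size=truth.mesh.pixel_size,
        meta={
            "phys": phys,
            "n_clipped": n_clipped,
            "kind": "fret_pair",
            "pattern": truth.pattern,
        },
    )


def render_calibration_images(
    phys: PhotophysicsParams,
    kind: str,
    truth: GroundTruthTissue | None = None,
) -> ChannelStack:
    """Render a calibration genotype: donor-only, acceptor-only or both
    fluorophores co-expressed on separate molecules (sensitized term zero).

    If no tissue is given, a default 60-cell sheet is generated from the
    photophysics seed so that calibration stacks are self-contained.
    """
    if kind not in ("donor_only", "acceptor_only", "coexpressed"):
        raise ValueError(f"unknown calibration kind {kind!r}")
    if truth is None:
        from .tissue import assign_ground_truth, generate_mesh

        mesh = generate_mesh(60, (512, 512), seed=phys.seed, geometry="sheet")
        truth = assign_ground_truth(mesh, "uniform", 0.0, 0.0)
    rho, emap = render_membrane_maps(truth, phys.membrane_width)
    cfp, yfp, fret = channels_from_density(
        rho,
        emap,
        phys,
        donor=kind != "acceptor_only",
        acceptor=kind != "donor_only",
        sensitized=False,
    )
    rng = np.random.default_rng(phys.seed + 1)
    (cfp_s, yfp_s, fret_s), n_clipped = _acquire([cfp, yfp, fret], phys, rng)
    return ChannelStack(
        cfp=cfp_s,
        yfp=yfp_s,
        fret=fret_s,
        bit_depth=phys.bit_depth,
        pixel_size=truth.mesh.pixel_size,
        meta={"phys": phys, "n_clipped": n_clipped, "kind": kind},
    )


def generate_pulsing_series(
    truth: GroundTruthTissue,
    n_timepoints: int = 8,
    interval_s: float = 60.0,
    phys: PhotophysicsParams | None = None,
) -> list[tuple[ChannelStack, GroundTruthTissue]]:
    """Render a pulsing time series (default t = 0..7 min at 60 s).

    Each time-point gets its own deformed mesh and an independent noise
    realisation (seeded from ``phys.seed`` + time index).
    """
    phys = phys or PhotophysicsParams()
    truths = pulsing_mesh_series(truth, n_timepoints, interval_s)
    out = []
    for k, truth_t in enumerate(truths):
        phys_t = replace(phys, seed=phys.seed + k)
        out.append((render_stack(truth_t, phys_t), truth_t))
    return out
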
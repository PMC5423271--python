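"""Synthetic multi-contrast brain phantoms with ground truth.

Geometric (not anatomical) phantoms: a nested ellipsoidal white-matter core,
gray-matter ribbon and CSF shell, decorated with the adjacency confounds that
plague T1-weighted-only segmentation of real heads:

* ``DURA`` — a thin sheet hugging the outer GM boundary, isointense to GM on
  the T1w channel but dark on FLAIR;
* ``VESSEL`` — bright tubes threaded through the CSF shell next to cortex
  (inflow-enhanced arteries), dark on FLAIR, high R2*;
* ``CONNECTIVE`` — patches outside the CSF shell, GM-like on T1w, dark on
  FLAIR;
* ``SUSCEPT_GM`` — a marked GM subregion where gradient-echo signal drops
  (T1w attenuated, R2* elevated) while spin-echo FLAIR is untouched.

Rendering draws each voxel from its label's per-modality mean and SD, applies
an optional smooth multiplicative bias field, and Rician (default) or
Gaussian noise.  When the T1w channel is requested as a multi-echo series,
echoes follow S0(label)·exp(−R2*(label)·TE) with S0 chosen so that the
echo-averaged image matches the contrast table — mirroring how an echo-combined
T1w image and an R2* map are both derived from one multi-echo acquisition.

Everything is deterministic given ``spec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .mixture import ClassSpec
from .relaxometry import MultiEchoSeries
from .volumes import ChannelStack, Volume

# label codes (integer NIfTI convention for ground truth)
BG, WM, GM, CSF, DURA, VESSEL, CONNECTIVE, SUSCEPT_GM = range(8)
LABEL_NAMES = {
    BG: "BG", WM: "WM", GM: "GM", CSF: "CSF", DURA: "DURA",
    VESSEL: "VESSEL", CONNECTIVE: "CONNECTIVE", SUSCEPT_GM: "SUSCEPT_GM",
}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

#: Paper-era acquisition echo times (ms) for the multi-echo T1w channel.
DEFAULT_ECHO_TIMES = (1.48, 2.98, 4.48, 5.98, 7.48)

# contrast table: label -> modality -> (mean, sd), arbitrary signal units.
# Encodes the confound structure: DURA/CONNECTIVE within 2% of GM on t1w but
# <= 50% of GM on flair; VESSEL >= 130% of GM on t1w; SUSCEPT_GM t1w
# attenuated x0.6 with flair unattenuated.
DEFAULT_CONTRAST = {
    "BG":         {"t1w": (30.0, 5.0),   "flair": (30.0, 5.0)},
    "WM":         {"t1w": (700.0, 35.0), "flair": (250.0, 25.0)},
    "GM":         {"t1w": (400.0, 40.0), "flair": (400.0, 40.0)},
    "CSF":        {"t1w": (120.0, 15.0), "flair": (60.0, 10.0)},
    "DURA":       {"t1w": (400.0, 40.0), "flair": (150.0, 20.0)},
    "VESSEL":     {"t1w": (520.0, 30.0), "flair": (100.0, 15.0)},
    "CONNECTIVE": {"t1w": (404.0, 40.0), "flair": (120.0, 18.0)},
    "SUSCEPT_GM": {"t1w": (240.0, 25.0), "flair": (400.0, 40.0)},
}

# plausible-order apparent relaxation rates (1/ms) per label; implementer
# defaults recorded here, not measured values.
DEFAULT_R2STAR = {
    "BG": 0.02, "WM": 0.045, "GM": 0.04, "CSF": 0.001, "DURA": 0.06,
    "VESSEL": 0.15, "CONNECTIVE": 0.05, "SUSCEPT_GM": 0.12,
}


@dataclass
class PhantomSpec:
    """Geometry, contrast, noise and seed of one synthetic phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # geometry (voxels)
    csf_margin: float = 2.5
    gm_thickness: float = 3.0
    dura_thickness: float = 1.5
    dura_arc_fraction: float = 0.35
    vessel_count: int = 3
    vessel_radius: float = 1.3
    connective_count: int = 2
    connective_radius: float = 2.5
    suscept_radius: float = 6.0
    # contrast / decay
    contrast_table: dict = field(default_factory=lambda: {
        k: {m: tuple(v) for m, v in d.items()} for k, d in DEFAULT_CONTRAST.items()
    })
    r2star_table: dict = field(default_factory=lambda: dict(DEFAULT_R2STAR))
    modalities: tuple[str, ...] = ("t1w_multiecho", "flair")
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    # degradation
    noise_model: str = "rician"          # "rician" | "gaussian" | "none"
    snr: float = 30.0                    # GM mean / noise sigma, per modality
    bias_order: int = 0                  # 0 disables the bias field
    bias_range: float = 0.0              # max |log-bias|, e.g. 0.15 for ±15%
    # low-contrast sector (occipital-style myelination confound): inside the
    # sector, WM t1w mean is pulled to (1 + factor) x GM mean
    low_contrast_sector: float = 0.0     # arc fraction of the +x hemisphere
    low_contrast_factor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gm_thickness < 1 or self.dura_thickness < 1:
            raise ValueError("thicknesses must be >= 1 voxel")
        if self.snr <= 0:
            raise ValueError("SNR must be > 0")
        missing = set(LABEL_NAMES.values()) - set(self.contrast_table)
        if missing:
            raise ValueError(f"contrast table missing labels: {sorted(missing)}")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        obj = asdict(self)
        obj["shape"] = list(self.shape)
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        obj = yaml.safe_load(Path(path).read_text())
        for key in ("shape", "voxel_size", "modalities", "echo_times"):
            if key in obj and isinstance(obj[key], list):
                obj[key] = tuple(obj[key])
        if "contrast_table" in obj:
            obj["contrast_table"] = {
                k: {m: tuple(v) for m, v in d.items()}
                for k, d in obj["contrast_table"].items()
            }
        return cls(**obj)


@dataclass
class PhantomTruth:
    """Ground-truth labels plus the parameters that generated a phantom."""

    labels: Volume
    contrast_table: dict
    r2star_table: dict
    bias_log_fields: dict | None = None   # channel -> Volume of log-bias
    seed: int = 0

    def mask(self, *label_names: str) -> Volume:
        codes = [LABEL_CODES[n] for n in label_names]
        return self.labels.like(np.isin(self.labels.data, codes))

    def class_mask(self, class_name: str) -> Volume:
        """Truth mask for a segmentation class (GM includes SUSCEPT_GM)."""
        mapping = {
            "GM": ("GM", "SUSCEPT_GM"),
            "WM": ("WM",),
            "CSF": ("CSF",),
            "OTHER": ("BG", "DURA", "VESSEL", "CONNECTIVE"),
        }
        return self.mask(*mapping[class_name])

    def brain_mask(self) -> Volume:
        """Everything except pure background — the segmentation mask."""
        return self.labels.like(self.labels.data != BG)

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels.data == code))
            for code, name in LABEL_NAMES.items()
        }


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _radial_field(spec: PhantomSpec) -> tuple[np.ndarray, float, np.ndarray]:
    """Dimensionless ellipsoidal radius u (u=1 at the outer CSF surface),
    the smallest semi-axis in voxels, and centred coordinates."""
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    semi = shape / 2.0 - 1.5          # leave background margin
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    coords = np.stack([ii - center[0], jj - center[1], kk - center[2]])
    u = np.sqrt(((coords / semi[:, None, None, None]) ** 2).sum(axis=0))
    return u, float(semi.min()), coords


def build_labels(spec: PhantomSpec) -> PhantomTruth:
    """Construct the ground-truth label volume for a spec (seeded)."""
    u, rmin, coords = _radial_field(spec)
    du = 1.0 / rmin                   # one voxel in u units (smallest axis)
    u_gm_outer = 1.0 - spec.csf_margin * du
    u_wm = u_gm_outer - spec.gm_thickness * du
    if u_wm <= 0.15:
        raise ValueError(
            "geometry does not fit: GM ribbon + CSF margin exceed the radius"
        )

    labels = np.full(spec.shape, BG, dtype=np.int16)
    labels[u <= 1.0] = CSF
    labels[u <= u_gm_outer] = GM
    labels[u <= u_wm] = WM

    rng = np.random.default_rng(spec.seed)

    # dura: thin sheet right outside the GM surface over a polar-angle arc
    if spec.dura_arc_fraction > 0:
        r = np.sqrt((coords**2).sum(axis=0))
        cos_polar = np.divide(coords[2], r, out=np.zeros_like(r), where=r > 0)
        arc = cos_polar >= np.cos(spec.dura_arc_fraction * np.pi)
        sheet = (u > u_gm_outer) & (u <= u_gm_outer + spec.dura_thickness * du)
        labels[sheet & arc & (labels == CSF)] = DURA

    # vessels: tubes along x, placed in the CSF shell near the GM surface
    for _ in range(spec.vessel_count):
        phi = rng.uniform(0, 2 * np.pi)
        shell_r = (u_gm_outer + 0.6 * spec.csf_margin * du / 2) * rmin
        cy = shell_r * np.cos(phi)
        cz = shell_r * np.sin(phi)
        dist = np.sqrt((coords[1] - cy) ** 2 + (coords[2] - cz) ** 2)
        tube = dist <= spec.vessel_radius
        near_gm = (u > u_gm_outer - 0.5 * du) & (u <= 1.0)
        labels[tube & near_gm & np.isin(labels, (CSF, DURA))] = VESSEL

    # connective patches just outside the CSF shell
    for _ in range(spec.connective_count):
        theta = rng.uniform(0.2 * np.pi, 0.8 * np.pi)
        phi = rng.uniform(0, 2 * np.pi)
        direction = np.array([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ])
        center = direction * (1.0 + (spec.connective_radius * 0.8) * du) * rmin
        dist = np.sqrt(((coords - center[:, None, None, None]) ** 2).sum(axis=0))
        blob = dist <= spec.connective_radius
        labels[blob & (labels == BG)] = CONNECTIVE

    # susceptibility zone: GM near the inferior (-z) pole
    if spec.suscept_radius > 0:
        pole = np.array([0.0, 0.0, -(u_gm_outer * rmin)])
        dist = np.sqrt(((coords - pole[:, None, None, None]) ** 2).sum(axis=0))
        zone = dist <= spec.suscept_radius
        labels[zone & (labels == GM)] = SUSCEPT_GM

    return PhantomTruth(
        labels=Volume(labels, spec.affine),
        contrast_table={k: dict(v) for k, v in spec.contrast_table.items()},
        r2star_table=dict(spec.r2star_table),
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _random_log_bias(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray | None:
    if spec.bias_order <= 0 or spec.bias_range <= 0:
        return None
    from .mixture import _poly_basis

    n_vox = int(np.prod(spec.shape))
    basis = _poly_basis(spec.shape, np.arange(n_vox), spec.bias_order)
    coeff = rng.standard_normal(basis.shape[1])
    fieldv = basis @ coeff
    # scale the stated range to the imaged object, not the empty corners
    u, _, _ = _radial_field(spec)
    region = (u <= 1.05).ravel()
    peak = np.max(np.abs(fieldv[region])) if region.any() else np.max(np.abs(fieldv))
    if peak > 0:
        fieldv *= spec.bias_range / peak
    return fieldv.reshape(spec.shape)


def _apply_noise(
    clean: np.ndarray, sigma: float, model: str, rng: np.random.Generator
) -> np.ndarray:
    if model == "none" or sigma <= 0:
        return clean
    if model == "gaussian":
        return clean + sigma * rng.standard_normal(clean.shape)
    # rician: magnitude of complex signal with iid Gaussian noise per channel
    re = clean + sigma * rng.standard_normal(clean.shape)
    im = sigma * rng.standard_normal(clean.shape)
    return np.sqrt(re**2 + im**2)


def _sector_mask(spec: PhantomSpec) -> np.ndarray:
    """Azimuthal sector around +x used for the low-contrast region."""
    _, _, coords = _radial_field(spec)
    r_xy = np.sqrt(coords[0] ** 2 + coords[1] ** 2)
    cos_az = np.divide(coords[0], r_xy, out=np.zeros_like(r_xy), where=r_xy > 0)
    return cos_az >= np.cos(spec.low_contrast_sector * np.pi)


def render_channels(
    truth: PhantomTruth, spec: PhantomSpec
) -> tuple[ChannelStack, MultiEchoSeries | None]:
    """Render the channel stack (and the multi-echo series if requested).

    Channel order: "t1w" (direct or echo-averaged), then "flair" and/or
    "r2star" as requested by ``spec.modalities``.  The stack mask excludes
    pure background, the usual skull-stripped analysis convention.
    """
    labels = truth.labels.data
    rng = np.random.default_rng(spec.seed + 1)  # decouple from geometry draws
    affine = spec.affine

    def label_image(modality: str, jitter: bool) -> np.ndarray:
        img = np.zeros(spec.shape, dtype=float)
        for name, code in LABEL_CODES.items():
            mean, sd = truth.contrast_table[name][modality]
            sel = labels == code
            img[sel] = mean
            if jitter and sd > 0:
                img[sel] += sd * rng.standard_normal(int(sel.sum()))
        return img

    use_noise = spec.noise_model != "none"
    gm_t1w = truth.contrast_table["GM"]["t1w"][0]

    # per-voxel tissue jitter for the T1w contrast (shared by all echoes so
    # the decay stays mono-exponential per voxel)
    t1w_clean = label_image("t1w", jitter=True)
    if spec.low_contrast_sector > 0:
        sector = _sector_mask(spec) & (labels == WM)
        lc_mean = gm_t1w * (1.0 + spec.low_contrast_factor)
        wm_mean, wm_sd = truth.contrast_table["WM"]["t1w"]
        t1w_clean[sector] += lc_mean - wm_mean

    bias_fields: dict[str, Volume] = {}

    def maybe_bias(img: np.ndarray, channel: str) -> np.ndarray:
        logb = _random_log_bias(spec, rng)
        if logb is None:
            return img
        bias_fields[channel] = Volume(logb, affine)
        gain = np.exp(logb)
        return img * (gain[..., None] if img.ndim == 4 else gain)

    channels: list[Volume] = []
    names: list[str] = []
    series: MultiEchoSeries | None = None

    sigma_t1w = gm_t1w / spec.snr if use_noise else 0.0

    if "t1w_multiecho" in spec.modalities:
        te = np.asarray(spec.echo_times)
        r2 = np.zeros(spec.shape)
        for name, code in LABEL_CODES.items():
            r2[labels == code] = truth.r2star_table[name]
        decay_mean = np.mean(np.exp(-r2[..., None] * te), axis=-1)
        s0 = t1w_clean / decay_mean     # echo average matches contrast table
        echo_clean = s0[..., None] * np.exp(-r2[..., None] * te)
        echo_clean = maybe_bias(echo_clean, "t1w")
        echoes = [
            Volume(
                _apply_noise(echo_clean[..., e], sigma_t1w, spec.noise_model, rng),
                affine.copy(),
            )
            for e in range(len(te))
        ]
        series = MultiEchoSeries(echoes, list(te))
        from .relaxometry import combine_echoes_mean

        channels.append(combine_echoes_mean(series))
        names.append("t1w")
    else:
        img = maybe_bias(t1w_clean, "t1w")
        channels.append(
            Volume(_apply_noise(img, sigma_t1w, spec.noise_model, rng), affine.copy())
        )
        names.append("t1w")

    if "flair" in spec.modalities:
        img = maybe_bias(label_image("flair", jitter=True), "flair")
        sigma = truth.contrast_table["GM"]["flair"][0] / spec.snr if use_noise else 0.0
        channels.append(
            Volume(_apply_noise(img, sigma, spec.noise_model, rng), affine.copy())
        )
        names.append("flair")

    if "r2star_truth" in spec.modalities:
        img = np.zeros(spec.shape)
        for name, code in LABEL_CODES.items():
            sel = labels == code
            img[sel] = truth.r2star_table[name]
            if use_noise:
                img[sel] += (
                    truth.r2star_table["GM"] / spec.snr
                ) * rng.standard_normal(int(sel.sum()))
        channels.append(Volume(img, affine.copy()))
        names.append("r2star")

    truth.bias_log_fields = bias_fields or None
    mask = truth.brain_mask()
    stack = ChannelStack(channels, names, mask=mask)
    return stack, series


def generate(spec: PhantomSpec) -> tuple[ChannelStack, MultiEchoSeries | None, PhantomTruth]:
    """build_labels + render_channels in one call."""
    truth = build_labels(spec)
    stack, series = render_channels(truth, spec)
    return stack, series, truth


# ---------------------------------------------------------------------------
# spatial priors and canonical suite
# ---------------------------------------------------------------------------

def make_priors(
    truth: PhantomTruth,
    class_specs: tuple[ClassSpec, ...] | list[ClassSpec] | None = None,
    sigma: float = 3.0,
    uniform_mix: float = 0.25,
) -> list[Volume]:
    """Atlas-like spatial priors from smoothed ground-truth tissue masks.

    One-hot maps of {GM (incl. susceptibility zone), WM, CSF, OTHER} are
    Gaussian-smoothed (``sigma`` voxels) and mixed with a uniform floor, then
    renormalised per voxel.  Heavy smoothing deliberately bleeds the GM prior
    onto adjacent dura/vessel sheets — the registration-free analog of warped
    population priors, which carry no information about these thin confounds.

    The OTHER prior is built from the membranous structures only (dura and
    connective tissue): background never enters the fit (it is outside the
    stack mask, and its bulk would just inflate the OTHER prior over the
    outer CSF shell), and vessels are absent from population tissue atlases,
    so they receive no prior support of their own — exactly the situation
    that lets bright vessels leak into gray matter when only the T1w channel
    is available.
    """
    from .mixture import DEFAULT_CLASS_SPECS

    class_specs = list(class_specs or DEFAULT_CLASS_SPECS)
    names = [s.name for s in class_specs]
    maps = []
    for name in names:
        if name == "OTHER":
            onehot = truth.mask("DURA", "CONNECTIVE").data.astype(float)
        else:
            onehot = truth.class_mask(name).data.astype(float)
        maps.append(gaussian_filter(onehot, sigma=sigma))
    P = np.stack(maps, axis=0)
    P /= np.clip(P.sum(axis=0, keepdims=True), 1e-12, None)
    C = len(names)
    P = (1.0 - uniform_mix) * P + uniform_mix / C
    P /= P.sum(axis=0, keepdims=True)
    return [truth.labels.like(P[i]) for i in range(C)]


def make_default_suite(
    seed: int = 0, shape: tuple[int, int, int] = (48, 48, 48)
) -> dict[str, tuple[ChannelStack, PhantomTruth]]:
    """Canonical named phantoms exercising each confound.

    "dura" (wide adherent sheet), "vessel" (more/thicker tubes),
    "susceptibility" (large dropout zone), "occipital-low-contrast" (GM/WM
    T1w contrast collapsed to 5% in a sector while FLAIR contrast is kept).
    """
    variants = {
        "dura": {"dura_arc_fraction": 0.5, "vessel_count": 2},
        "vessel": {"vessel_count": 5, "vessel_radius": 1.6},
        "susceptibility": {"suscept_radius": 9.0},
        "occipital-low-contrast": {
            "low_contrast_sector": 0.25, "suscept_radius": 0.0,
        },
    }
    out = {}
    for i, (name, kwargs) in enumerate(variants.items()):
        spec = PhantomSpec(shape=shape, seed=seed + i, **kwargs)
        stack, _, truth = generate(spec)
        out[name] = (stack, truth)
    return out
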
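"""Synthetic full-body MSI phantoms with known ground truth.

The generator emulates the sagittal zebrafish sections the pipeline targets:
a muscle body containing liver, brain, eye and gill regions plus two adipose
depots (a visceral blob and a subepidermal ribbon), each tissue carrying a
distinct lipid signature.  A subset of features is planted as adipose-
enriched at fold changes 1.5-2.8 over the non-adipose tissues — the range
reported for high-confidence adipose lipids — while null features share one
mean everywhere.  Pixel noise is multiplicative lognormal with a configurable
within-tissue CV (default 15%, matching the observed intra-tissue
reproducibility band), split between a smooth per-feature spatial field and
white pixel noise so that 3x3-ROI means retain realistic dispersion; each
replicate is scaled by a global factor mimicking day-to-day source drift.
Optional M+1 isotopologue satellites are added at +1.00336 Da with relative
abundance 0.0107 * C / 0.9893 for a carbon count C.

Geometry is deliberately schematic (axis-aligned ellipses and ribbons):
the phantoms exercise the pipeline's statistics, not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import MS2Spectrum, fragment_rules
from .chem import ADDUCTS, LipidRecord, adduct_mz, parse_shorthand
from .io import MSIDataset, TissueMask

__all__ = [
    "PanelLipid",
    "PhantomSpec",
    "GroundTruth",
    "default_panel",
    "build_layout",
    "simulate_dataset",
    "simulate_ms2",
    "simulate_lesa_extracts",
    "ISOTOPE_DELTA_DA",
]

ISOTOPE_DELTA_DA = 1.00336
_C13_RATIO = 0.0107 / 0.9893  # per carbon M+1 abundance relative to M


@dataclass(frozen=True)
class PanelLipid:
    """One planted lipid: species, adduct, abundance and enrichment plan."""

    lipid: LipidRecord
    adduct_name: str
    base_intensity: float
    adipose_fold: float = 1.0
    tissue_weights: dict = field(default_factory=dict, compare=False)
    role: str = "null"  # enriched | null | marker | shared

    @property
    def mz(self) -> float:
        return adduct_mz(self.lipid.monoisotopic_mass, ADDUCTS[self.adduct_name])

    def mean_for(self, label: str) -> float:
        w = self.tissue_weights.get(label, 1.0)
        if label == "adipose":
            w *= self.adipose_fold
        return self.base_intensity * w


def default_panel() -> list[PanelLipid]:
    """The 50-feature negative-mode panel behind the default phantom.

    16 adipose-enriched free/oxidized fatty acids at folds 1.5-2.8, 14 null
    phospholipids, 10 tissue markers (two per non-adipose organ) and 10
    abundant shared membrane lipids that dominate the TIC everywhere.
    """
    panel: list[PanelLipid] = []
    enriched = [
        "FA(12:0)", "FA(14:0)", "FA(16:2)", "FA(16:1)", "FA(16:0)",
        "FA(16:2;O)", "FA(17:1)", "FA(17:0)", "FA(16:0;O)", "FA(18:0)",
        "FA(18:2;O)", "FA(18:1;O)", "FA(20:0)", "FA(22:0)", "FA(22:6;O)",
        "FA(24:0)",
    ]
    folds = np.linspace(1.5, 2.8, len(enriched))
    for name, fold in zip(enriched, folds):
        panel.append(PanelLipid(parse_shorthand(name), "[M-H]-", 80.0,
                                adipose_fold=float(fold), role="enriched"))
    nulls = [
        "PE(34:1)", "PE(34:2)", "PE(36:2)", "PE(36:4)", "PE(38:4)",
        "PE(38:6)", "PE(40:5)", "PI(32:1)", "PI(36:2)", "PI(38:4)",
        "PG(32:1)", "PG(36:2)", "PS(36:1)", "PS(38:4)",
    ]
    for name in nulls:
        panel.append(PanelLipid(parse_shorthand(name), "[M-H]-", 200.0,
                                role="null"))
    markers = {
        "muscle": ["PI(40:6)", "PG(40:6)"],
        "liver": ["PE(40:6)", "PI(38:3)"],
        "brain": ["PS(40:6)", "PE(38:5)"],
        "eye": ["PS(38:3)", "PI(36:3)"],
        "gill": ["PEe(38:7)", "PG(38:5)"],
    }
    for tissue, names in markers.items():
        for name in names:
            panel.append(PanelLipid(
                parse_shorthand(name), "[M-H]-", 100.0,
                tissue_weights={tissue: 8.0}, role="marker"))
    shared = [
        "PC(32:0)", "PC(34:2)", "PC(34:1)", "PC(36:4)", "PC(36:2)",
        "PC(38:6)", "PC(38:4)", "PC(40:6)", "SM(34:1;O2)", "SM(42:2;O2)",
    ]
    for name in shared:
        panel.append(PanelLipid(parse_shorthand(name), "[M+HCOO]-", 400.0,
                                role="shared"))
    return panel


@dataclass
class PhantomSpec:
    """Study conditions for one simulated multi-replicate section series."""

    seed: int = 1
    width: int = 64
    height: int = 32
    n_replicates: int = 3
    polarity: str = "negative"
    noise_cv: float = 0.15
    spatial_noise_fraction: float = 0.5
    spatial_block: int = 8
    scale_range: tuple[float, float] = (0.8, 1.25)
    baseline_level: float = 2.0
    isotope_satellites: bool = False
    panel: list[PanelLipid] = field(default_factory=default_panel)
    # overall lipid yield per tissue (multiplies every feature; removed by
    # TIC normalization, so it shapes raw TIC contrasts only)
    tissue_tic_scale: dict = field(default_factory=lambda: {
        "muscle": 1.0, "liver": 1.35, "brain": 1.2, "eye": 1.1,
        "gill": 0.9, "adipose": 1.0,
    })

    def __post_init__(self):
        if not (0.0 < self.noise_cv < 1.0):
            raise ValueError("noise_cv must be in (0, 1)")
        if any(p.adipose_fold <= 0 for p in self.panel):
            raise ValueError("all fold changes must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery scoring."""

    mask: TissueMask
    feature_mz: np.ndarray
    panel: list[PanelLipid]
    enriched_mz: tuple[float, ...]
    null_mz: tuple[float, ...]
    tissue_means: dict  # mz -> {label: mean}
    replicate_scales: tuple[float, ...]
    satellite_mz: tuple[float, ...] = ()


def _ellipse(yy, xx, cx, cy, rx, ry):
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def build_layout(spec: PhantomSpec) -> TissueMask:
    """Deterministic multi-tissue layout for the spec's seed and grid size.

    Regions are carved out of a muscle body ellipse in a fixed order so they
    stay disjoint; organ centers are jittered by the seed (which moves the
    adipose depots between seeds while keeping the anatomy plausible).
    """
    w, h = spec.width, spec.height
    if w < 16 or h < 16:
        raise ValueError(f"grid {w}x{h} too small to place all regions (min 16)")
    rng = np.random.default_rng([spec.seed, 0xA11CE])
    jit = lambda scale: float(rng.uniform(-scale, scale))  # noqa: E731

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.full((h, w), "background", dtype="<U16")
    bcx, bcy, brx, bry = w / 2, h / 2, 0.46 * w, 0.40 * h
    body = _ellipse(yy, xx, bcx, bcy, brx, bry)
    labels[body] = "muscle"

    def carve(region, name):
        sel = region & (labels == "muscle")
        labels[sel] = name

    carve(_ellipse(yy, xx, 0.17 * w + jit(0.02 * w), 0.40 * h + jit(0.02 * h),
                   0.085 * w, 0.135 * h), "brain")
    carve(_ellipse(yy, xx, 0.10 * w + jit(0.01 * w), 0.55 * h + jit(0.02 * h),
                   0.045 * w, 0.09 * h), "eye")
    x0, x1 = int(round(0.26 * w)), max(int(round(0.26 * w)) + 1, int(round(0.30 * w)))
    carve((xx >= x0) & (xx < x1), "gill")
    carve(_ellipse(yy, xx, 0.40 * w + jit(0.02 * w), 0.62 * h + jit(0.02 * h),
                   0.09 * w, 0.14 * h), "liver")
    carve(_ellipse(yy, xx, 0.60 * w + jit(0.03 * w), 0.60 * h + jit(0.03 * h),
                   0.09 * w, 0.115 * h), "adipose")
    # subepidermal ribbon: a 2-pixel band along the dorsal body edge
    inner = _ellipse(yy, xx, bcx, bcy, max(brx - 2, 1), max(bry - 2, 1))
    ribbon = body & ~inner & (yy < bcy) & (xx >= 0.40 * w) & (xx <= 0.80 * w)
    carve(ribbon, "adipose")

    mask = TissueMask(width=w, height=h, labels=labels)
    for required in ("adipose", "muscle", "liver", "brain"):
        if mask.count(required) == 0:
            raise ValueError(f"grid too small: region {required!r} is empty")
    return mask


def _smooth_field(rng, h, w, block):
    """Unit-variance field, piecewise constant over block x block tiles."""
    gh, gw = -(-h // block), -(-w // block)
    coarse = rng.standard_normal((gh, gw))
    return np.kron(coarse, np.ones((block, block)))[:h, :w]


def simulate_dataset(spec: PhantomSpec) -> tuple[list[MSIDataset], GroundTruth]:
    """Simulate ``n_replicates`` sections plus the planted ground truth."""
    mask = build_layout(spec)
    h, w = spec.height, spec.width
    flat_labels = mask.flat()

    panel = sorted(spec.panel, key=lambda p: p.mz)
    mz_list = [p.mz for p in panel]
    if len(set(np.round(mz_list, 4))) != len(mz_list):
        raise ValueError("panel m/z values collide")
    sat_parent: list[int] = []
    sat_mz: list[float] = []
    if spec.isotope_satellites:
        for j, p in enumerate(panel):
            sat_parent.append(j)
            sat_mz.append(p.mz + ISOTOPE_DELTA_DA)
    axis = np.array(mz_list + sat_mz)
    order = np.argsort(axis)
    axis = axis[order]
    col_of = {int(o): k for k, o in enumerate(order)}  # original idx -> axis col

    sigma2 = np.log1p(spec.noise_cv ** 2)
    sig_s = np.sqrt(spec.spatial_noise_fraction * sigma2)
    sig_w = np.sqrt((1 - spec.spatial_noise_fraction) * sigma2)

    # planted per-tissue means (pre replicate scaling)
    labels_present = [l for l in np.unique(flat_labels) if l != "background"]
    mean_matrix = np.zeros((len(panel), len(flat_labels)))
    tissue_means: dict = {}
    for j, p in enumerate(panel):
        per_label = {
            lab: p.mean_for(lab) * spec.tissue_tic_scale.get(lab, 1.0)
            for lab in labels_present}
        tissue_means[p.mz] = per_label
        for lab in labels_present:
            mean_matrix[j, flat_labels == lab] = per_label[lab]

    scales = []
    datasets = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, 0x5EC, r])
        scale = 1.0 if r == 0 else float(rng.uniform(*spec.scale_range))
        scales.append(scale)
        inten = np.zeros((len(flat_labels), len(axis)), dtype=np.float64)
        for j, p in enumerate(panel):
            sf = _smooth_field(rng, h, w, spec.spatial_block).reshape(-1)
            white = rng.standard_normal(len(flat_labels))
            mu = mean_matrix[j]
            live = mu > 0
            vals = np.zeros(len(flat_labels))
            vals[live] = np.exp(
                np.log(mu[live]) - sigma2 / 2
                + sig_s * sf[live] + sig_w * white[live])
            col = col_of[j]
            inten[:, col] += vals
        if spec.isotope_satellites:
            for k, j in enumerate(sat_parent):
                ratio = _C13_RATIO * panel[j].lipid.formula.get("C", 0)
                inten[:, col_of[len(panel) + k]] += inten[:, col_of[j]] * ratio
        inten += rng.exponential(spec.baseline_level, size=inten.shape)
        inten *= scale
        datasets.append(MSIDataset(
            replicate_id=f"rep{r + 1}",
            polarity=spec.polarity,
            width=w, height=h,
            mz_axis=axis,
            intensities=inten.astype(np.float32),
            metadata={"seed": spec.seed, "replicate_scale": scale},
        ))

    truth = GroundTruth(
        mask=mask,
        feature_mz=np.array(mz_list),
        panel=panel,
        enriched_mz=tuple(p.mz for p in panel if p.adipose_fold > 1.0),
        null_mz=tuple(p.mz for p in panel if p.adipose_fold == 1.0),
        tissue_means=tissue_means,
        replicate_scales=tuple(scales),
        satellite_mz=tuple(sat_mz),
    )
    return datasets, truth


def simulate_ms2(
    lipid: LipidRecord,
    adduct_name: str,
    seed: int = 0,
    n_noise_peaks: int = 5,
    noise_level: float = 0.02,
) -> MS2Spectrum:
    """Simulate a centroided fragmentation spectrum for a lipid/adduct.

    Contains the precursor, every class-diagnostic rule fragment (exact
    m/z), and low-level random noise peaks.  Raises for classes without a
    fragment rule.
    """
    adduct = ADDUCTS[adduct_name]
    precursor = adduct_mz(lipid.monoisotopic_mass, adduct)
    frags = fragment_rules(lipid, adduct)
    rng = np.random.default_rng([seed, 0xF4A6])
    peaks = [(precursor, 100.0)]
    for i, f in enumerate(sorted(frags, reverse=True)):
        peaks.append((f, 60.0 * 0.8 ** i))
    lo = max(50.0, 0.1 * precursor)
    for _ in range(n_noise_peaks):
        peaks.append((float(rng.uniform(lo, precursor - 1.0)),
                      float(rng.uniform(0.1, 100 * noise_level))))
    peaks.sort()
    return MS2Spectrum(precursor_mz=precursor,
                       polarity=adduct.polarity,
                       fragments=peaks)


def simulate_lesa_extracts(
    mask: TissueMask,
    n_sites: int,
    standards: list[tuple[LipidRecord, str, float]],
    seed: int = 0,
    panel: list[PanelLipid] | None = None,
    standard_cv: float = 0.13,
) -> list[list[tuple[float, float]]]:
    """Simulate surface-extraction MS1 peak lists from adipose sites.

    ``standards`` holds ``(lipid, adduct_name, nominal_intensity)`` spikes,
    reproduced per site with lognormal CV (default 13%, the reproducibility
    observed for spiked internal standards).  Tissue lipids, when a panel is
    given, are drawn from the adipose signature with the same CV.
    """
    if n_sites == 0:
        return []
    adipose = mask.tissue_pixels()
    adipose = adipose[mask.flat()[adipose] == "adipose"]
    if len(adipose) < n_sites:
        raise ValueError(
            f"insufficient adipose area: {len(adipose)} pixels < {n_sites} sites")
    rng = np.random.default_rng([seed, 0x1E5A])
    rng.choice(adipose, size=n_sites, replace=False)  # site positions (unused masses)
    sigma2 = np.log1p(standard_cv ** 2)
    spectra = []
    for _ in range(n_sites):
        peaks = []
        for lipid, adduct_name, nominal in standards:
            mz = adduct_mz(lipid.monoisotopic_mass, ADDUCTS[adduct_name])
            val = np.exp(np.log(nominal) - sigma2 / 2
                         + np.sqrt(sigma2) * rng.standard_normal())
            peaks.append((mz, float(val)))
        if panel is not None:
            for p in panel:
                mean = p.mean_for("adipose")
                val = np.exp(np.log(mean) - sigma2 / 2
                             + np.sqrt(sigma2) * rng.standard_normal())
                peaks.append((p.mz, float(val)))
        peaks.sort()
        spectra.append(peaks)
    return spectra


def with_noise_cv(spec: PhantomSpec, cv: float) -> PhantomSpec:
    """Copy of a spec with a different within-tissue noise CV."""
    return replace(spec, noise_cv=cv)


def simulate_feature_matrices(
    mask: TissueMask,
    folds: np.ndarray,
    n_replicates: int = 3,
    noise_cv: float = 0.15,
    seed: int = 1,
    base_intensity: float = 100.0,
    spatial_noise_fraction: float = 0.5,
    spatial_block: int = 8,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Feature x tissue-pixel matrices with planted adipose folds.

    A matrix-level phantom sharing the full generator's noise model
    (lognormal with a smooth per-feature spatial field plus white pixel
    noise), used for large feature panels where explicit lipid identities
    are irrelevant — e.g. null-calibration studies with every fold at 1.0.
    Returns per-replicate matrices restricted to tissue pixels, plus the
    adipose and non-adipose column indices.
    """
    folds = np.asarray(folds, dtype=float)
    if np.any(folds <= 0):
        raise ValueError("folds must be positive")
    flat = mask.flat()
    tissue = np.nonzero(flat != "background")[0]
    is_adipose = flat[tissue] == "adipose"
    adipose_idx = np.nonzero(is_adipose)[0]
    nonadipose_idx = np.nonzero(~is_adipose)[0]
    h, w = mask.height, mask.width
    sigma2 = np.log1p(noise_cv ** 2)
    sig_s = np.sqrt(spatial_noise_fraction * sigma2)
    sig_w = np.sqrt((1 - spatial_noise_fraction) * sigma2)
    mu = np.full((len(folds), len(tissue)), base_intensity)
    mu[:, is_adipose] *= folds[:, None]
    matrices = []
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, 0xFA57, r])
        M = np.empty_like(mu)
        for j in range(len(folds)):
            sf = _smooth_field(rng, h, w, spatial_block).reshape(-1)[tissue]
            white = rng.standard_normal(len(tissue))
            M[j] = np.exp(np.log(mu[j]) - sigma2 / 2 + sig_s * sf + sig_w * white)
        matrices.append(M)
    return matrices, adipose_idx, nonadipose_idx
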
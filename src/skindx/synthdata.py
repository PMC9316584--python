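"""Synthetic multi-slice skin-biopsy case generator.

Renders cartoon skin histology with exact ground truth: horizontal strata
(background, stratum corneum, epidermis, dermis), disk-shaped epidermal
nests inside the epidermis and dermal nests inside the dermis.  The
diagnostic class drives the nest statistics:

* melanoma dermal nests (DMN-M) appear **only** in invasive classes
  (T1a, T1b), with T1b denser than T1a — the class-logic rule that lets
  benign-class dermal nests be relabeled as nevus type downstream;
* MIS carries more epidermal nests than MMD;
* the *total* dermal-nest count is class-constant, so when
  ``decoy_contrast = 0`` (melanoma and nevus nests share one RGB
  appearance) the invasive sub-classes are indistinguishable from RGB
  alone and the DMN-M mask channel is the only T1a/T1b signal.

Each case has one slice carrying the diagnosis-defining content and the
ROI; the other slices are rendered at a severity drawn at or below the
case severity, emulating slides where most sections are unremarkable.
Everything is deterministic in (config, case seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .labels import DIAGNOSIS_CLASSES, MASK_CODES, DiagnosisClass
from .maskops import read_mask, write_mask, write_rgb

#: Reference area (pixels) against which nest densities are expressed.
REF_AREA = 192 * 192

#: Vertical band fractions (top to bottom): BG, COR, EP, DE.
BAND_FRACTIONS = {"BG": 0.10, "COR": 0.10, "EP": 0.22, "DE": 0.58}

#: Table-1-derived class proportions after the I/II merge (61/60/72/47 of 240).
DEFAULT_CLASS_PROPORTIONS = (61 / 240, 60 / 240, 72 / 240, 47 / 240)

MANIFEST_COLUMNS = ("case_id", "slice_id", "rgb_path", "mask_path",
                    "diagnosis", "split", "roi")


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the package's study conditions."""

    slice_size: Tuple[int, int] = (192, 192)        # H, W at nominal 20x
    slices_per_case: Tuple[int, int] = (1, 4)       # inclusive uniform range
    class_proportions: Tuple[float, ...] = DEFAULT_CLASS_PROPORTIONS
    #: epidermal-nest count per REF_AREA, indexed by severity rank
    epn_density: Tuple[float, ...] = (2.0, 8.0, 5.0, 5.0)
    #: total dermal-nest count per REF_AREA (class-constant by design)
    dmn_density: Tuple[float, ...] = (8.0, 8.0, 8.0, 8.0)
    #: melanoma share of the dermal nests, by severity rank
    dmn_m_density: Tuple[float, ...] = (0.0, 0.0, 2.0, 6.0)
    nest_radius_range: Tuple[int, int] = (8, 11)
    #: per-tissue mean RGB
    colors: Dict[str, Tuple[float, float, float]] = field(default_factory=lambda: {
        "BG": (235.0, 235.0, 240.0),
        "COR": (244.0, 220.0, 228.0),
        "EP": (160.0, 110.0, 180.0),
        "DE": (232.0, 170.0, 190.0),
        "EPN": (120.0, 75.0, 150.0),
        "DMN_N": (112.0, 70.0, 145.0),
    })
    #: RGB offset of a melanoma nest at decoy_contrast = 1
    dmn_m_color_delta: Tuple[float, float, float] = (70.0, -40.0, -50.0)
    noise_sd: float = 8.0
    #: 0 -> DMN-M visually identical to DMN-N; 1 -> fully distinct
    decoy_contrast: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must sum to 1, got {sum(self.class_proportions)}")
        if len(self.class_proportions) != len(DIAGNOSIS_CLASSES):
            raise ValueError("need one proportion per diagnosis class")
        h, w = self.slice_size
        if h < 64 or w < 64:
            raise ValueError(f"slice_size must be at least 64x64, got {h}x{w}")
        if not 0.0 <= self.decoy_contrast <= 1.0:
            raise ValueError("decoy_contrast must lie in [0, 1]")
        lo, hi = self.slices_per_case
        if lo < 1 or hi < lo:
            raise ValueError(f"bad slices_per_case range {self.slices_per_case}")
        dermis_h = int(h * BAND_FRACTIONS["DE"])
        if 2 * self.nest_radius_range[1] > dermis_h:
            raise ValueError(
                f"infeasible geometry: nest diameter up to "
                f"{2 * self.nest_radius_range[1]} px exceeds the dermis band "
                f"height {dermis_h} px")

    def dmn_m_color(self) -> Tuple[float, float, float]:
        base = self.colors["DMN_N"]
        d = self.dmn_m_color_delta
        return tuple(base[i] + self.decoy_contrast * d[i] for i in range(3))


@dataclass
class SlideCase:
    """One biopsy case: ordered (rgb, mask) slices plus its diagnosis."""

    case_id: str
    diagnosis: DiagnosisClass
    slices: List[Tuple[np.ndarray, np.ndarray]]
    #: (slice_index, (r0, c0, r1, c1)) half-open rectangle, or None
    roi: Optional[Tuple[int, Tuple[int, int, int, int]]] = None
    provenance_seed: Optional[int] = None

    def __post_init__(self):
        if not self.slices:
            raise ValueError("a case needs at least one slice")
        for i, (rgb, mask) in enumerate(self.slices):
            if rgb.shape[:2] != mask.shape:
                raise ValueError(
                    f"slice {i}: rgb {rgb.shape[:2]} vs mask {mask.shape}")
        if self.roi is not None:
            idx, (r0, c0, r1, c1) = self.roi
            h, w = self.slices[idx][1].shape
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"ROI {self.roi} outside slice {idx} ({h}x{w})")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def _band_rows(h: int) -> Dict[str, Tuple[int, int]]:
    """Half-open row ranges of the four strata."""
    r_cor = int(h * BAND_FRACTIONS["BG"])
    r_ep = r_cor + int(h * BAND_FRACTIONS["COR"])
    r_de = r_ep + int(h * BAND_FRACTIONS["EP"])
    return {"BG": (0, r_cor), "COR": (r_cor, r_ep),
            "EP": (r_ep, r_de), "DE": (r_de, h)}


def _paint_disks(mask: np.ndarray, rng: np.random.Generator, band: Tuple[int, int],
                 n: int, radii: Tuple[int, int], code: int) -> None:
    h, w = mask.shape
    r0, r1 = band
    for _ in range(n):
        rad = int(rng.integers(radii[0], radii[1] + 1))
        cy_lo, cy_hi = r0 + rad, r1 - rad
        if cy_hi <= cy_lo:      # band too thin for this radius
            continue
        cy = int(rng.integers(cy_lo, cy_hi))
        cx = int(rng.integers(rad, max(rad + 1, w - rad)))
        yy, xx = np.ogrid[-rad:rad + 1, -rad:rad + 1]
        disk = yy * yy + xx * xx <= rad * rad
        ys = slice(cy - rad, cy + rad + 1)
        xs = slice(max(0, cx - rad), min(w, cx + rad + 1))
        sub = disk[:, max(0, rad - cx):disk.shape[1] - max(0, cx + rad + 1 - w)]
        mask[ys, xs][sub] = code


def _counts_for(severity: int, cfg: SynthConfig, area: int) -> Tuple[int, int, int]:
    """(EPN count, DMN-M count, DMN-N count) for one slice at a severity."""
    scale = area / REF_AREA
    n_epn = int(round(cfg.epn_density[severity] * scale))
    n_dmn = int(round(cfg.dmn_density[severity] * scale))
    n_m = int(round(cfg.dmn_m_density[severity] * scale))
    n_m = min(n_m, n_dmn)
    if severity >= DiagnosisClass.T1a:
        n_m = max(n_m, 1)       # invasive slices must carry melanoma nests
    return n_epn, n_m, n_dmn - n_m


def _render_slice(rng: np.random.Generator, severity: int,
                  cfg: SynthConfig) -> Tuple[np.ndarray, np.ndarray]:
    h, w = cfg.slice_size
    bands = _band_rows(h)
    mask = np.empty((h, w), dtype=np.uint8)
    for name, (a, b) in bands.items():
        mask[a:b] = MASK_CODES[name]
    n_epn, n_m, n_n = _counts_for(severity, cfg, h * w)
    _paint_disks(mask, rng, bands["EP"], n_epn, cfg.nest_radius_range,
                 MASK_CODES["EPN"])
    _paint_disks(mask, rng, bands["DE"], n_n, cfg.nest_radius_range,
                 MASK_CODES["DMN_N"])
    _paint_disks(mask, rng, bands["DE"], n_m, cfg.nest_radius_range,
                 MASK_CODES["DMN_M"])

    palette = np.zeros((len(MASK_CODES), 3))
    for name, code in MASK_CODES.items():
        palette[code] = cfg.dmn_m_color() if name == "DMN_M" else cfg.colors[name]
    rgb = palette[mask] + rng.normal(0.0, cfg.noise_sd, (h, w, 3))
    return np.clip(rgb, 0, 255).astype(np.uint8), mask


def _nest_roi(mask: np.ndarray, margin: int = 4) -> Tuple[int, int, int, int]:
    """Half-open bounding rectangle of all nest pixels, with a margin."""
    nest = mask >= MASK_CODES["EPN"]
    rows = np.flatnonzero(nest.any(axis=1))
    cols = np.flatnonzero(nest.any(axis=0))
    h, w = mask.shape
    if rows.size == 0:          # no nests at all: fall back to the dermis band
        a, b = _band_rows(h)["DE"]
        return (a, 0, b, w)
    return (max(0, rows[0] - margin), max(0, cols[0] - margin),
            min(h, rows[-1] + margin + 1), min(w, cols[-1] + margin + 1))


def generate_case(config: SynthConfig, diagnosis: DiagnosisClass,
                  case_seed: int) -> SlideCase:
    """Generate one deterministic synthetic case.

    Exactly one slice (the ROI slice) is rendered at the case severity;
    the remaining slices draw a severity uniformly at or below it.
    """
    diagnosis = DiagnosisClass(diagnosis)
    rng = np.random.default_rng([config.seed, int(case_seed)])
    lo, hi = config.slices_per_case
    n_slices = int(rng.integers(lo, hi + 1))
    roi_index = int(rng.integers(n_slices))
    slices = []
    for i in range(n_slices):
        sev = int(diagnosis) if i == roi_index else int(
            rng.integers(0, int(diagnosis) + 1))
        slices.append(_render_slice(rng, sev, config))
    roi_rect = _nest_roi(slices[roi_index][1])
    return SlideCase(
        case_id=f"case{case_seed:05d}",
        diagnosis=diagnosis,
        slices=slices,
        roi=(roi_index, roi_rect),
        provenance_seed=int(case_seed),
    )


def largest_remainder(proportions: Sequence[float], n: int) -> List[int]:
    """Integer allocation of n items by the largest-remainder method.

    Ties in the fractional part are broken toward the lower index, so the
    allocation is deterministic.
    """
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.lexsort((np.arange(len(raw)), -(raw - base)))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def split_class_counts(counts: Sequence[int]) -> Tuple[List[int], List[int]]:
    """50/50 split of per-class counts; odd remainders alternate sides.

    Guarantees each half's per-class count differs from half the class
    total by at most 1/2 (i.e. by at most 1 case).
    """
    train, test = [], []
    flip = True
    for c in counts:
        t = c // 2
        if c % 2:
            t += 1 if flip else 0
            flip = not flip
        train.append(t)
        test.append(c - t)
    return train, test


def generate_dataset(config: SynthConfig, n_cases: int, out_dir: Union[str, Path],
                     force: bool = False) -> pd.DataFrame:
    """Write a synthetic dataset (PNG slices + masks + manifest CSV).

    Class counts follow ``config.class_proportions`` by largest-remainder
    rounding; cases are tagged with a fixed 50/50 train/test split that
    preserves the class distribution.  Refuses to overwrite an existing
    manifest unless ``force``.
    """
    if n_cases < 4:
        raise ValueError("need at least 4 cases (one per diagnostic class)")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"manifest already exists: {manifest_path} (pass force=True)")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    counts = largest_remainder(config.class_proportions, n_cases)
    n_train, _ = split_class_counts(counts)

    rows = []
    case_seed = 0
    for cls, n_cls, n_tr in zip(DIAGNOSIS_CLASSES, counts, n_train):
        for j in range(n_cls):
            case = generate_case(config, cls, case_seed)
            split = "train" if j < n_tr else "test"
            for i, (rgb, mask) in enumerate(case.slices):
                rgb_rel = f"images/{case.case_id}_s{i}.png"
                mask_rel = f"masks/{case.case_id}_s{i}.png"
                write_rgb(out_dir / rgb_rel, rgb)
                write_mask(out_dir / mask_rel, mask)
                roi_str = ""
                if case.roi is not None and case.roi[0] == i:
                    roi_str = ":".join(str(v) for v in case.roi[1])
                rows.append({
                    "case_id": case.case_id, "slice_id": f"s{i}",
                    "rgb_path": rgb_rel, "mask_path": mask_rel,
                    "diagnosis": cls.name, "split": split, "roi": roi_str,
                })
            case_seed += 1
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(manifest_path, index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def parse_roi(roi_str: str) -> Optional[Tuple[int, int, int, int]]:
    if not roi_str:
        return None
    parts = tuple(int(v) for v in roi_str.split(":"))
    if len(parts) != 4:
        raise ValueError(f"bad ROI field {roi_str!r}")
    return parts


def audit_class_logic(manifest_path: Union[str, Path]) -> List[Tuple[str, int]]:
    """Report (case_id, slice_index) pairs violating the class/nest rule.

    A violation is any melanoma-dermal-nest pixel on a slice of a case
    whose diagnosis is MMD or MIS (benign-class cases may only contain
    nevus dermal nests).  An intact generated dataset yields an empty list.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    violations = []
    for _, row in manifest.iterrows():
        cls = DiagnosisClass.from_string(row["diagnosis"])
        if cls >= DiagnosisClass.T1a:
            continue
        mask = read_mask(root / row["mask_path"])
        if np.any(mask == MASK_CODES["DMN_M"]):
            violations.append((row["case_id"], int(row["slice_id"].lstrip("s"))))
    return violations


def load_case(manifest: pd.DataFrame, root: Union[str, Path],
              case_id: str) -> SlideCase:
    """Reassemble a SlideCase from manifest rows and files on disk."""
    from .maskops import read_rgb  # local import to avoid cycle at module load
    sel = manifest[manifest["case_id"] == case_id]
    if sel.empty:
        raise KeyError(f"case {case_id!r} not in manifest")
    sel = sel.sort_values("slice_id", key=lambda s: s.str.lstrip("s").astype(int))
    root = Path(root)
    slices, roi = [], None
    for i, (_, row) in enumerate(sel.iterrows()):
        slices.append((read_rgb(root / row["rgb_path"]),
                       read_mask(root / row["mask_path"])))
        rect = parse_roi(row["roi"])
        if rect is not None:
            roi = (i, rect)
    return SlideCase(case_id=case_id,
                     diagnosis=DiagnosisClass.from_string(sel.iloc[0]["diagnosis"]),
                     slices=slices, roi=roi)
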
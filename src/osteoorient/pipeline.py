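"""End-to-end orchestration: file I/O, the metrics pipeline, trend demo.

A run consumes either files on disk (SHG image, labeled cell mask,
track CSV, mask pair) or a named synthetic scenario, computes every
applicable metric, and writes a metrics TSV plus a JSON manifest that
suffices to reproduce the run bit-identically.

The metrics table has one row per (image_id, cell_label) with the
field-level row keyed ``cell_label='FIELD'``:

========================  =============================================
column                    meaning
========================  =============================================
cfoi                      field CFOI (FIELD row only)
major_deg                 major spectral orientation (FIELD row only)
eccentricity              per-cell equivalent-ellipse eccentricity
oci                       per-cell OCI; FIELD row holds the OCI of the
                          mean radius profile over all cells
cdi                       per-cell deformation index (if a mask pair)
mean_velocity_um_min      per-track mean speed; FIELD row holds the
                          cohort mean
n_cells                   number of labeled cells (FIELD row only)
========================  =============================================

Missing metrics are left as nulls (empty TSV cells), never zeros.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    AngularProfile,
    DEFAULT_PIXEL_SIZE_UM,
    IntensityImage,
    LabeledMask,
    TrackSet,
)
from .correlation import DEFAULT_TAU_DEG, oci
from .dynamics import cdi_table, cohort_velocity
from .errors import DegenerateInputError, DegenerateRegionError, FormatError, ValidationError
from .morphology import mean_eccentricity, radius_profile
from .spectral import (
    DEFAULT_LOWPASS_PERIOD_PX,
    DEFAULT_SIGMA_FRACTION,
    cfoi,
    fiber_profile,
    major_orientation,
)
from .synthetic import (
    make_cell_masks,
    make_deforming_masks,
    make_fiber_texture,
    make_tracks,
    scenario_specs,
)

METRIC_COLUMNS = [
    "image_id",
    "cell_label",
    "cfoi",
    "major_deg",
    "eccentricity",
    "oci",
    "cdi",
    "mean_velocity_um_min",
    "n_cells",
]


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def read_intensity_image(
    path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> IntensityImage:
    """Read a single-channel TIFF/PNG as a float image scaled to [0, 1]."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(
            f"{path}: expected a single-channel image, got {arr.shape[-1]} channels"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return IntensityImage(arr, pixel_size_um=pixel_size_um, meta={"source": str(path)})


def write_intensity_image(img: IntensityImage, path: str | Path) -> None:
    """Write as 16-bit single-channel TIFF (values clipped to [0, 1])."""
    import tifffile

    data = np.clip(img.pixels, 0.0, 1.0)
    tifffile.imwrite(str(path), (data * 65535).round().astype(np.uint16))


def read_labeled_mask(
    path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> LabeledMask:
    """Read an integer label TIFF/PNG."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label image must have an integer dtype")
    return LabeledMask(arr.astype(np.int32), pixel_size_um=pixel_size_um)


def write_labeled_mask(mask: LabeledMask, path: str | Path) -> None:
    """Write as 16-bit label TIFF."""
    import tifffile

    if mask.labels.max() > 65535:
        raise ValidationError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything a metrics run needs; JSON-serializable.

    Either ``scenario`` names a synthetic stage (``day10like`` /
    ``day21like``) or at least one of the file inputs is given.
    """

    scenario: str | None = None
    image_path: str | None = None
    mask_path: str | None = None
    tracks_path: str | None = None
    mask_t0_path: str | None = None
    mask_t1_path: str | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    crop_size_px: int = 512
    crop_x: int = 0
    crop_y: int = 0
    lowpass_period_px: float = DEFAULT_LOWPASS_PERIOD_PX
    sigma_fraction: float = DEFAULT_SIGMA_FRACTION
    tau_deg: int = DEFAULT_TAU_DEG
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario is None and not any(
            (self.image_path, self.mask_path, self.tracks_path,
             self.mask_t0_path, self.mask_t1_path)
        ):
            raise ValidationError("config needs a scenario or at least one input file")
        for name in ("pixel_size_um", "crop_size_px", "lowpass_period_px",
                     "sigma_fraction"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be positive")
        if self.crop_x < 0 or self.crop_y < 0:
            raise ValidationError("crop origin must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"bad config JSON: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------

def field_radius_profile(mask: LabeledMask) -> AngularProfile:
    """Mean of the per-cell radius profiles: the field-level g(theta)."""
    ids = mask.label_ids()
    profiles = [radius_profile(mask, int(lab)).values for lab in ids]
    return AngularProfile(np.mean(profiles, axis=0), kind="cell_radius")


def _synthetic_inputs(config: PipelineConfig):
    """Generate scenario inputs: image, mask, tracks, deforming pair."""
    fibers, cells = scenario_specs(config.scenario, config.seed)
    img = make_fiber_texture(fibers)
    mask = make_cell_masks(
        cells, fibers.width_px, fiber_orientation_deg=fibers.mean_orientation_deg
    )
    # early-stage cells move faster and deform more than late-stage ones
    fast = config.scenario == "day10like"
    tracks = make_tracks(
        n_cells=cells.n_cells,
        speed_um_min=0.5 if fast else 0.2,
        seed=config.seed + 20_000,
    )
    mask_t0, mask_t1 = make_deforming_masks(
        mask, deformation_level=0.5, seed=config.seed + 30_000
    )
    return img, mask, tracks, (mask_t0, mask_t1)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Compute every applicable metric; optionally write TSV + manifest.

    Returns the metrics table (see module docstring for columns).  With
    ``config.out_dir`` set, writes ``metrics.tsv`` and ``manifest.json``
    there; a repeat run with the same config writes byte-identical
    output.
    """
    image = mask = tracks = None
    mask_pair: tuple[LabeledMask, LabeledMask] | None = None
    image_id = config.scenario or "files"
    if config.scenario is not None:
        image, mask, tracks, mask_pair = _synthetic_inputs(config)
    else:
        if config.image_path:
            image = read_intensity_image(config.image_path, config.pixel_size_um)
            image_id = Path(config.image_path).stem
        if config.mask_path:
            mask = read_labeled_mask(config.mask_path, config.pixel_size_um)
        if config.tracks_path:
            tracks = TrackSet.from_csv(config.tracks_path)
        if config.mask_t0_path and config.mask_t1_path:
            mask_pair = (
                read_labeled_mask(config.mask_t0_path, config.pixel_size_um),
                read_labeled_mask(config.mask_t1_path, config.pixel_size_um),
            )

    rows: list[dict] = []
    field_row: dict = {"image_id": image_id, "cell_label": "FIELD"}

    f_profile = None
    if image is not None:
        crop = image.crop(config.crop_x, config.crop_y, config.crop_size_px)
        f_profile = fiber_profile(
            crop,
            lowpass_period_px=config.lowpass_period_px,
            sigma_fraction=config.sigma_fraction,
        )
        part = major_orientation(f_profile)
        field_row["cfoi"] = cfoi(f_profile)
        field_row["major_deg"] = part.major_deg

    if mask is not None:
        mean_ecc, cell_table = mean_eccentricity(mask)
        field_row["eccentricity"] = mean_ecc
        field_row["n_cells"] = len(cell_table)
        per_cell: dict[int, dict] = {
            int(r.label): {
                "image_id": image_id,
                "cell_label": int(r.label),
                "eccentricity": r.eccentricity,
            }
            for r in cell_table.itertuples()
        }
        if f_profile is not None:
            for lab in per_cell:
                try:
                    g = radius_profile(mask, lab)
                    per_cell[lab]["oci"] = oci(f_profile, g, config.tau_deg).oci
                except (DegenerateRegionError, DegenerateInputError):
                    pass  # leave as null
            try:
                field_row["oci"] = oci(
                    f_profile, field_radius_profile(mask), config.tau_deg
                ).oci
            except (DegenerateRegionError, DegenerateInputError):
                pass
        if mask_pair is not None:
            for r in cdi_table(*mask_pair).itertuples():
                per_cell.setdefault(
                    int(r.label),
                    {"image_id": image_id, "cell_label": int(r.label)},
                )["cdi"] = r.cdi
        rows.extend(per_cell[k] for k in sorted(per_cell))
    elif mask_pair is not None:
        for r in cdi_table(*mask_pair).itertuples():
            rows.append(
                {"image_id": image_id, "cell_label": int(r.label), "cdi": r.cdi}
            )

    if tracks is not None:
        vel_table, vmean, _vsd = cohort_velocity(tracks)
        field_row["mean_velocity_um_min"] = vmean
        for r in vel_table.itertuples():
            rows.append(
                {
                    "image_id": image_id,
                    "cell_label": f"track{int(r.track_id)}",
                    "mean_velocity_um_min": r.mean_velocity_um_min,
                }
            )

    table = pd.DataFrame([field_row] + rows).reindex(columns=METRIC_COLUMNS)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics_tsv(table, out / "metrics.tsv")
        manifest = {
            "config": dataclasses.asdict(config),
            "package": "osteoorient",
            "version": __version__,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return table


def write_metrics_tsv(table: pd.DataFrame, path) -> None:
    """Canonical TSV output: tab-separated, UTF-8, '.' decimal, nulls empty.

    Floats are written with shortest round-trip repr, so re-reading the
    file reproduces the in-memory values exactly.
    """
    table.to_csv(path, sep="\t", index=False)


def read_metrics_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.reindex(columns=METRIC_COLUMNS)


# --------------------------------------------------------------------------
# trend demo
# --------------------------------------------------------------------------

def demo_trends(
    seeds: list[int], out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Early-to-late stage contrast over several seeds.

    Runs the ``day10like`` and ``day21like`` scenarios for each seed and
    reports, for the early-to-late transition, the fraction of seeds in
    which field CFOI rises, mean eccentricity falls, and field OCI
    falls — the orientation-coupling signature of maturing bone.

    Returns ``(per_seed_table, fractions)``; with ``out_dir`` set, also
    writes ``trends.tsv`` and a bar-chart ``trends.png``.
    """
    if len(seeds) < 5:
        raise ValidationError("trend demo needs at least 5 seeds")
    records = []
    for seed in seeds:
        per_stage = {}
        for stage in ("day10like", "day21like"):
            t = run_pipeline(PipelineConfig(scenario=stage, seed=seed))
            fld = t[t["cell_label"] == "FIELD"].iloc[0]
            per_stage[stage] = fld
            records.append(
                {
                    "seed": seed,
                    "stage": stage,
                    "cfoi": fld["cfoi"],
                    "eccentricity": fld["eccentricity"],
                    "oci": fld["oci"],
                    "mean_velocity_um_min": fld["mean_velocity_um_min"],
                }
            )
    table = pd.DataFrame(records)
    wide = table.pivot(index="seed", columns="stage")
    fractions = {
        "cfoi_rises": float(
            (wide[("cfoi", "day10like")] < wide[("cfoi", "day21like")]).mean()
        ),
        "eccentricity_falls": float(
            (wide[("eccentricity", "day10like")]
             > wide[("eccentricity", "day21like")]).mean()
        ),
        "oci_falls": float(
            (wide[("oci", "day10like")] > wide[("oci", "day21like")]).mean()
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "trends.tsv", sep="\t", index=False)
        _plot_trends(table, out / "trends.png")
    return table, fractions


def _plot_trends(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["cfoi", "eccentricity", "oci"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(10, 3.2))
    for ax, metric in zip(axes, metrics):
        for stage, color in (("day10like", "C0"), ("day21like", "C1")):
            sub = table[table["stage"] == stage]
            ax.scatter([stage] * len(sub), sub[metric], s=18, color=color, alpha=0.7)
            ax.bar(stage, sub[metric].mean(), color=color, alpha=0.25, width=0.6)
        ax.set_title(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
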
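"""End-to-end workflow: preprocess -> register -> CTVIvol -> CTVIHU ->
fuse -> resample back to the original exhale grid -> (optional) evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path
import time

import numpy as np
import scipy

from . import __version__
from .evaluation import EvalResult, evaluate
from .fusion import fuse_hector
from .registration import RegistrationConfig, RegistrationResult, register
from .ventilation import VentilationMap, ctvi_hu, specific_volume_change, transport_to_exhale
from .volume import (
    GeometryRecord,
    LungMask,
    PreprocessedPair,
    ScalarVolume,
    preprocess_pair,
    read_mask,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a single-case run."""

    inhale: str
    exhale: str
    inhale_mask: str
    exhale_mask: str
    output_dir: str
    refvi: str | None = None          # reference ventilation on the exhale grid
    grid_size: int = 128
    margin: int = 10
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    median_patch: int = 5
    background: float = -1.0          # sentinel outside the lung mask
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "registration"}
        d["registration"] = self.registration.to_dict()
        return d


@dataclass
class HectorOutputs:
    """All intermediate and final products of one case."""

    pair: PreprocessedPair
    registration: RegistrationResult
    ctvi_vol: VentilationMap          # on the processed exhale grid
    ctvi_hu: VentilationMap
    ctvi_hector: VentilationMap
    eval_result: EvalResult | None = None


def run_pair(
    inhale: ScalarVolume,
    exhale: ScalarVolume,
    inhale_mask: LungMask,
    exhale_mask: LungMask,
    grid_size: int = 128,
    margin: int = 10,
    registration_config: RegistrationConfig | None = None,
    median_patch: int = 5,
    background: float = -1.0,
) -> HectorOutputs:
    """Run the full hybrid-metric computation in memory.

    Returns the three ventilation maps on the processed (cropped,
    resampled) exhale grid together with the registration result and the
    preprocessed pair, from which the maps can be resampled back to the
    original anatomy with :func:`map_to_original_grid`.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    pair = preprocess_pair(inhale, exhale, inhale_mask, exhale_mask,
                           grid_size=grid_size, margin=margin)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reg = register(pair.inhale_norm, pair.exhale_norm, pair.inhale_mask,
                   registration_config)
    timings["register"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    svol = specific_volume_change(reg.divcurl, pair.inhale_mask)
    vol_map = transport_to_exhale(svol, reg.displacement, pair.exhale_mask)
    hu_map = ctvi_hu(pair.exhale_hu, pair.exhale_mask, filter_patch=median_patch)
    hector = fuse_hector(vol_map, hu_map, pair.exhale_mask, background=background)
    timings["metrics"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        logger.info("stage %-10s %.2f s", stage, dt)
    return HectorOutputs(pair=pair, registration=reg, ctvi_vol=vol_map,
                         ctvi_hu=hu_map, ctvi_hector=hector)


def map_to_original_grid(
    vmap: VentilationMap,
    record: GeometryRecord,
    template: ScalarVolume,
    mask_orig: LungMask,
    background: float = -1.0,
) -> ScalarVolume:
    """Trilinearly resample a processed-grid map onto the original exhale grid.

    ``template`` supplies the original geometry metadata; values outside
    the original exhale lung mask are set to ``background``.  Before
    interpolation the map is extended outside its processed-grid mask
    with nearest in-mask values, so background sentinels never bleed
    into lung-edge voxels.
    """
    from scipy import ndimage

    extended = vmap.values.copy()
    inside = vmap.mask.values
    if not inside.all():
        _, nearest = ndimage.distance_transform_edt(~inside, return_indices=True)
        extended[~inside] = extended[tuple(idx[~inside] for idx in nearest)]

    coords_orig = np.indices(record.original_shape, dtype=np.float64)
    coords_proc = np.stack([
        (coords_orig[a] - record.crop_offset[a]) / record.scale[a] for a in range(3)
    ])
    vals = ndimage.map_coordinates(extended, coords_proc, order=1, mode="nearest")
    vals[~mask_orig.values] = background
    return ScalarVolume(vals, spacing=template.spacing, origin=template.origin,
                        direction=template.direction, unit="none")


def run_hector(config: PipelineConfig) -> dict:
    """File-based single-case pipeline; writes the three maps as NIfTI plus
    a JSON provenance record, and evaluates against a reference ventilation
    image when one is given.  Deterministic given inputs and config."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        inhale = read_volume(config.inhale, unit="hu")
        exhale = read_volume(config.exhale, unit="hu")
        inhale_mask = read_mask(config.inhale_mask, phase="inhale")
        exhale_mask = read_mask(config.exhale_mask, phase="exhale")

        stage = "pipeline"
        outputs = run_pair(inhale, exhale, inhale_mask, exhale_mask,
                           grid_size=config.grid_size, margin=config.margin,
                           registration_config=config.registration,
                           median_patch=config.median_patch,
                           background=config.background)

        stage = "resample to original grid"
        record = outputs.pair.geometry
        written: dict[str, str] = {}
        for name, vmap in (("ctvi_vol", outputs.ctvi_vol),
                           ("ctvi_hu", outputs.ctvi_hu),
                           ("ctvi_hector", outputs.ctvi_hector)):
            vol = map_to_original_grid(vmap, record, exhale, exhale_mask,
                                       background=config.background)
            path = out_dir / f"{name}.nii.gz"
            write_volume(vol, path)
            written[name] = str(path)

        eval_result = None
        if config.refvi is not None:
            stage = "evaluate"
            ref = read_volume(config.refvi)
            hector_orig = read_volume(written["ctvi_hector"])
            refmap = VentilationMap(ref.values, mask=exhale_mask, label="truth")
            hectormap = VentilationMap(hector_orig.values, mask=exhale_mask,
                                       label="hector")
            eval_result = evaluate(hectormap, refmap, exhale_mask)
            logger.info("spearman=%.3f dsc_high=%.3f dsc_low=%.3f n=%d",
                        eval_result.spearman, eval_result.dsc_high,
                        eval_result.dsc_low, eval_result.n_voxels)

        stage = "provenance"
        provenance = {
            "config": config.to_dict(),
            "versions": {"hectorvi": __version__, "numpy": np.__version__,
                         "scipy": scipy.__version__},
            "geometry": record.to_dict(),
            "final_data_term": outputs.registration.final_data_term,
            "outputs": written,
        }
        if eval_result is not None:
            provenance["evaluation"] = eval_result.to_dict()
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
        written["provenance"] = str(out_dir / "provenance.json")
        return {"outputs": written, "evaluation": eval_result}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc
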
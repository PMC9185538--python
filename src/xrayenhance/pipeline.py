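"""End-to-end radiograph enhancement and the parameter-sweep harness.

The five-stage procedure:

1. histogram equalization of the input (global contrast stretch);
2. NSST decomposition into one low-frequency band and per-level
   directional high-frequency bands;
3. AGCWD contrast correction of the low-frequency band;
4. gradient-domain guided filtering with detail boosting of every
   high-frequency band (denoise, then amplify the residual by ξ);
5. inverse NSST and clipping to [0, 1].

The pipeline contains no randomness: identical input and configuration
give byte-identical output.  Clipping (rather than rescaling) is applied
to the reconstruction because detail boosting can overshoot the unit
range and a global rescale would undo the contrast gained in stage 3;
the clipped-pixel fraction is logged.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .agcwd import DEFAULT_ALPHA, agcwd_enhance_raster
from .gdgf import GdgfParams, enhance_subband
from .imaging import GrayImage, histogram_equalize
from .metrics import report
from .nsst import NsstConfig, nsst_forward, nsst_inverse

__all__ = ["EnhanceConfig", "enhance", "sweep_levels", "sweep_directions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnhanceConfig:
    """Full pipeline configuration; the defaults are the operating point
    for radiographs: 4 decomposition levels with 4 directions each,
    GDGF at ς=16, λ=0.5, ξ=5, AGCWD α=0.5, equalization on."""

    nsst: NsstConfig = field(default_factory=NsstConfig)
    gdgf: GdgfParams = field(default_factory=GdgfParams)
    agcwd_alpha: float = DEFAULT_ALPHA
    equalize_first: bool = True
    agcwd_bypass: bool = False
    metric_scale: float | None = 255.0

    @classmethod
    def from_yaml(cls, path) -> "EnhanceConfig":
        """Load a flat key/value YAML config (every CLI flag has a twin)."""
        raw = yaml.safe_load(open(path)) or {}
        cfg = cls()
        levels = int(raw.get("levels", cfg.nsst.levels))
        dirs = raw.get("dirs", None)
        if dirs is not None:
            shear = tuple(int(x) for x in str(dirs).split(","))
        elif levels != cfg.nsst.levels:
            shear = (cfg.nsst.shear_params[0],) * levels
        else:
            shear = cfg.nsst.shear_params
        return cls(
            nsst=NsstConfig(levels=levels, shear_params=shear),
            gdgf=GdgfParams(
                radius=int(raw.get("radius", cfg.gdgf.radius)),
                lam=float(raw.get("lam", cfg.gdgf.lam)),
                xi=float(raw.get("xi", cfg.gdgf.xi)),
                eps=float(raw.get("eps", cfg.gdgf.eps)),
                weight_mode=str(raw.get("weight_mode", cfg.gdgf.weight_mode)),
            ),
            agcwd_alpha=float(raw.get("alpha", cfg.agcwd_alpha)),
            equalize_first=bool(raw.get("equalize", cfg.equalize_first)),
            agcwd_bypass=bool(raw.get("agcwd_bypass", cfg.agcwd_bypass)),
        )


def enhance(img: GrayImage, cfg: EnhanceConfig | None = None) -> GrayImage:
    """Run the five-stage enhancement; output has the input's shape, [0, 1]."""
    if cfg is None:
        cfg = EnhanceConfig()
    t0 = time.perf_counter()
    work = histogram_equalize(img) if cfg.equalize_first else img
    logger.debug("equalize done (%.3fs)", time.perf_counter() - t0)

    bands = nsst_forward(work, cfg.nsst)
    logger.debug(
        "NSST forward: j=%d dirs=%s low[min=%.3g max=%.3g σ=%.3g]",
        cfg.nsst.levels, cfg.nsst.directions,
        bands.low.min(), bands.low.max(), bands.low.std(),
    )

    if not cfg.agcwd_bypass:
        bands.low = agcwd_enhance_raster(bands.low, cfg.agcwd_alpha)
    for k, level_bands in enumerate(bands.high):
        for d, band in enumerate(level_bands):
            level_bands[d] = enhance_subband(band, cfg.gdgf)
            logger.debug(
                "band L%d D%d: min=%.3g max=%.3g σ=%.3g",
                k + 1, d, level_bands[d].min(), level_bands[d].max(), level_bands[d].std(),
            )

    recon = nsst_inverse(bands)
    clipped = float(np.mean((recon < 0.0) | (recon > 1.0)))
    if clipped > 0:
        logger.debug("clipping %.2f%% of reconstructed pixels", 100 * clipped)
    logger.debug("pipeline total %.3fs", time.perf_counter() - t0)
    return img.with_pixels(np.clip(recon, 0.0, 1.0))


def _row(img: GrayImage, out: GrayImage, cfg: EnhanceConfig) -> dict:
    rep = report(out, cfg.metric_scale)
    return {
        "levels": cfg.nsst.levels,
        "directions": ",".join(str(d) for d in cfg.nsst.directions),
        "AG": rep.AG,
        "H": rep.H,
        "SF": rep.SF,
        "EI": rep.EI,
    }


def sweep_levels(img: GrayImage, cfg: EnhanceConfig | None = None,
                 j_range=(1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Enhance at each decomposition level count; one metric row per j.

    The per-level shearing parameter is held fixed at the first entry of
    the base configuration while j varies.
    """
    if cfg is None:
        cfg = EnhanceConfig()
    l = cfg.nsst.shear_params[0]
    rows = []
    for j in j_range:
        cfg_j = replace(cfg, nsst=NsstConfig(levels=int(j), shear_params=(l,) * int(j)))
        rows.append(_row(img, enhance(img, cfg_j), cfg_j))
    return pd.DataFrame(rows)


def sweep_directions(img: GrayImage, cfg: EnhanceConfig | None = None,
                     shear_sets=((2, 2, 2, 2), (3, 3, 3, 3), (4, 4, 4, 4))) -> pd.DataFrame:
    """Enhance under several per-level shearing parameterizations; one
    metric row per shear set (level count follows each set's length)."""
    if cfg is None:
        cfg = EnhanceConfig()
    rows = []
    for shear in shear_sets:
        shear = tuple(int(s) for s in shear)
        cfg_s = replace(cfg, nsst=NsstConfig(levels=len(shear), shear_params=shear))
        rows.append(_row(img, enhance(img, cfg_s), cfg_s))
    return pd.DataFrame(rows)
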
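"""Pipeline configuration: one nested, strictly validated record per stage.

YAML and JSON are both accepted; unknown keys are rejected so a typo never
silently falls back to a default.  Every run logs the resolved config and
seed, which is what makes deterministic stages reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger("fasf_tle")

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessConfig(_Strict):
    enabled: bool = True
    skull_strip: bool = True
    threshold_method: str = Field("otsu", pattern="^(otsu|quantile)$")
    threshold_quantile: float = Field(0.5, ge=0.0, le=1.0)
    morph_radius: int = Field(2, ge=0)
    bias_correct: bool = True
    smoothing_sigma_mm: float = Field(8.0, gt=0)
    bias_max_iter: int = Field(20, ge=1)
    bias_tol: float = Field(1e-3, gt=0)
    bias_n_classes: int = Field(3, ge=1)
    normalize: bool = True
    median: bool = True
    median_window: int = Field(3, ge=1)


class FPCMConfig(_Strict):
    c: int = Field(3, ge=1)
    M: float = Field(2.0, gt=1.0)
    Q: float = Field(2.0, gt=1.0)
    eta: str | float = "auto"
    eta_scale: float = Field(1.0, gt=0)
    epsilon: float = Field(1e-5, gt=0)
    max_iter: int = Field(100, ge=1)
    init: str = Field("quantile", pattern="^(quantile|kmeanspp)$")


class FeaturesConfig(_Strict):
    slice_axis: int = Field(2, ge=0, le=2)
    slice_mode: str = Field("mid", pattern="^(mid|all)$")
    lbp_points: int = Field(8, ge=4, le=8)


class DGWOSettings(_Strict):
    n_agents: int = Field(10, ge=4)
    max_iter: int = Field(30, ge=1)
    c1_start: float = 2.0
    c1_end: float = 0.0
    c3_start: float = 0.9
    c3_end: float = 0.4
    c4: float = 1.5
    c5: float = 1.5
    switch_threshold: float = Field(0.5, ge=0.0, le=1.0)
    binarize_threshold: float = Field(0.5, gt=0.0, lt=1.0)
    cv_folds: int = Field(3, ge=2)
    algorithm1_position_update: bool = False


class HAETNSettings(_Strict):
    conv_filters: int = Field(64, ge=1)
    conv_kernel: int = Field(3, ge=1)
    pool: int = Field(2, ge=1)
    lstm_hidden: int = Field(128, ge=1)
    attn_heads: int = Field(8, ge=1)
    ffn_hidden: int = Field(2048, ge=1)
    transformer_dropout: float = Field(0.1, ge=0.0, lt=1.0)
    dense_units: int = Field(64, ge=1)
    dense_dropout: float = Field(0.5, ge=0.0, lt=1.0)
    n_classes: int = Field(2, ge=2)
    fuse_handcrafted: bool = False
    two_residual: bool = False
    epochs: int = Field(15, ge=1)
    batch_size: int = Field(32, ge=1)
    learning_rate: float = Field(0.01, gt=0)
    momentum: float = Field(0.9, ge=0.0, lt=1.0)
    max_grad_norm: float = Field(5.0, ge=0.0)
    max_restarts: int = Field(3, ge=0)
    restart_patience: int = Field(5, ge=1)
    restart_threshold: float = Field(0.65, ge=0.0, le=1.0)


class EvalConfig(_Strict):
    k: int = Field(5, ge=2)


class PipelineConfig(_Strict):
    seed: int = 0
    preprocess: PreprocessConfig = PreprocessConfig()
    fpcm: FPCMConfig = FPCMConfig()
    features: FeaturesConfig = FeaturesConfig()
    dgwo: DGWOSettings = DGWOSettings()
    haetn: HAETNSettings = HAETNSettings()
    eval: EvalConfig = EvalConfig()

    def log_resolved(self) -> None:
        logger.info("resolved config (seed=%d): %s", self.seed, self.model_dump())


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file; missing file or ``None`` means defaults."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else (yaml.safe_load(text) or {})
    data.update(overrides)
    cfg = PipelineConfig.model_validate(data)
    cfg.log_resolved()
    return cfg
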
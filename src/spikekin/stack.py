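"""Two-level stacked generalization fusing the FR and ISI decoders.

Level-0 holds one recurrent decoder per feature stream (firing rate and
interspike interval).  The training rows are split contiguously in time:
the earlier part trains the level-0 models; their predictions on the later
part (z-scored with that part's statistics) become the inputs of the
level-1 combiner, so the combiner never sees data its inputs were fitted
on.  Conventional single-stream decoders are available as baselines.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import DecoderDataset, Normalization
from .rnn import (
    RNNParams,
    TrainConfig,
    init_params,
    lm_train,
    params_from_dict,
    params_to_dict,
    rnn_forward,
)

__all__ = [
    "StackModel",
    "split_training",
    "train_stack",
    "stack_predict",
    "train_baseline",
    "save_stack",
    "load_stack",
]

DEFAULT_SPLIT_RATIO = 0.5
LEVEL1_HIDDEN = (4, 4)


@dataclass
class StackModel:
    """Trained level-0 FR/ISI decoders plus the level-1 combiner."""

    level0_fr: RNNParams
    level0_isi: RNNParams
    level1: RNNParams
    level1_norm: Normalization
    split_ratio: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.level0_fr.n_out + self.level0_isi.n_out
        if self.level1.p != total:
            raise ValueError(
                f"level-1 input dim {self.level1.p} != level-0 output dim {total}"
            )


def _check_aligned(data_fr: DecoderDataset, data_isi: DecoderDataset) -> None:
    if data_fr.n_rows != data_isi.n_rows:
        raise ValueError("FR and ISI datasets must have equal row counts")
    if np.max(np.abs(data_fr.times - data_isi.times)) > 1e-9:
        raise ValueError("FR and ISI datasets are not row-aligned in time")


def split_training(
    data_fr: DecoderDataset,
    data_isi: DecoderDataset,
    ratio: float = DEFAULT_SPLIT_RATIO,
) -> tuple[DecoderDataset, DecoderDataset, DecoderDataset, DecoderDataset]:
    """Contiguous-in-time split at floor(n*ratio), identical for both streams."""
    _check_aligned(data_fr, data_isi)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = data_fr.n_rows
    cut = int(np.floor(n * ratio))
    if cut == 0 or cut == n:
        raise ValueError("split leaves an empty part")
    return (
        data_fr.slice_rows(0, cut),
        data_isi.slice_rows(0, cut),
        data_fr.slice_rows(cut),
        data_isi.slice_rows(cut),
    )


def _feature_meta(data: DecoderDataset) -> dict:
    return {k: data.meta.get(k) for k in ("kinds", "unit_ids", "fs", "lag_count")}


def _init_model(data: DecoderDataset, cfg: TrainConfig, hidden: tuple[int, int]) -> RNNParams:
    """Seeded init with the readout pre-fit by least squares.

    Solving c against the initial hidden trajectories puts the first
    outputs on the targets' scale (the net has no output bias), which keeps
    the early damped steps well-conditioned.
    """
    params = init_params(
        p=data.n_inputs,
        q=hidden[0],
        r=hidden[1],
        n_out=data.targets.shape[1],
        seed=cfg.seed,
        scale=cfg.weight_init_scale,
    )
    _, (_, y2) = rnn_forward(params, data.inputs)
    c, *_ = np.linalg.lstsq(y2, data.targets, rcond=None)
    params.c = c
    return params


def train_baseline(
    data: DecoderDataset,
    cfg: TrainConfig,
    hidden: tuple[int, int] = (8, 8),
) -> tuple[RNNParams, list[dict]]:
    """Single-stream conventional decoder trained on the full training set."""
    return lm_train(_init_model(data, cfg, hidden), data, cfg)


def train_stack(
    data_fr: DecoderDataset,
    data_isi: DecoderDataset,
    cfg0: TrainConfig,
    cfg1: TrainConfig,
    ratio: float = DEFAULT_SPLIT_RATIO,
    hidden0: tuple[int, int] = (8, 8),
    hidden1: tuple[int, int] = LEVEL1_HIDDEN,
) -> StackModel:
    """Train the full stacked decoder.

    Level-0 FR and ISI decoders fit the earlier split part of their own
    stream; both then predict the later part, and the concatenated
    prediction matrix (z-scored with later-part statistics) trains the
    level-1 combiner against the later-part targets.
    """
    p0_fr, p0_isi, p1_fr, p1_isi = split_training(data_fr, data_isi, ratio)

    fr_params, _ = train_baseline(p0_fr, cfg0, hidden=hidden0)
    isi_cfg = TrainConfig(**{**cfg0.__dict__, "seed": cfg0.seed + 1})
    isi_params, _ = train_baseline(p0_isi, isi_cfg, hidden=hidden0)

    pred_fr, _ = rnn_forward(fr_params, p1_fr.inputs)
    pred_isi, _ = rnn_forward(isi_params, p1_isi.inputs)
    level1_in = np.hstack([pred_fr, pred_isi])
    offset = level1_in.mean(axis=0)
    scale = level1_in.std(axis=0)
    scale = np.where(scale > 1e-12, scale, 1.0)
    cols = [f"fr_pred_{j}" for j in ("hip", "knee", "ankle")] + [
        f"isi_pred_{j}" for j in ("hip", "knee", "ankle")
    ]
    norm = Normalization(offset, scale, cols)
    level1_data = DecoderDataset(
        inputs=norm.apply(level1_in),
        targets=p1_fr.targets,
        times=p1_fr.times,
        fs=p1_fr.fs,
        lag_count=0,
        normalization=norm,
        meta={"level": 1},
    )
    level1_params, _ = lm_train(
        _init_model(level1_data, cfg1, hidden1), level1_data, cfg1
    )

    return StackModel(
        level0_fr=fr_params,
        level0_isi=isi_params,
        level1=level1_params,
        level1_norm=norm,
        split_ratio=ratio,
        metadata={"fr": _feature_meta(data_fr), "isi": _feature_meta(data_isi)},
    )


def stack_predict(
    model: StackModel,
    data_fr: DecoderDataset,
    data_isi: DecoderDataset,
    check_meta: bool = True,
) -> np.ndarray:
    """Full forward chain; returns (n, 3) joint-angle estimates in degrees."""
    _check_aligned(data_fr, data_isi)
    if check_meta and model.metadata:
        for key, data in (("fr", data_fr), ("isi", data_isi)):
            want = model.metadata.get(key)
            got = _feature_meta(data)
            if want is not None and want != got:
                bad = [k for k in want if want.get(k) != got.get(k)]
                raise ValueError(
                    f"{key} feature config mismatch on keys {bad}: "
                    f"model={want}, data={got}"
                )
    pred_fr, _ = rnn_forward(model.level0_fr, data_fr.inputs)
    pred_isi, _ = rnn_forward(model.level0_isi, data_isi.inputs)
    level1_in = model.level1_norm.apply(np.hstack([pred_fr, pred_isi]))
    out, _ = rnn_forward(model.level1, level1_in)
    return out


def save_stack(model: StackModel, path) -> None:
    payload = {
        "level0_fr": params_to_dict(model.level0_fr),
        "level0_isi": params_to_dict(model.level0_isi),
        "level1": params_to_dict(model.level1),
        "level1_norm": {
            "offset": model.level1_norm.offset.tolist(),
            "scale": model.level1_norm.scale.tolist(),
            "columns": model.level1_norm.columns,
        },
        "split_ratio": model.split_ratio,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_stack(path) -> StackModel:
    with open(path) as fh:
        d = json.load(fh)
    return StackModel(
        level0_fr=params_from_dict(d["level0_fr"]),
        level0_isi=params_from_dict(d["level0_isi"]),
        level1=params_from_dict(d["level1"]),
        level1_norm=Normalization(
            np.asarray(d["level1_norm"]["offset"]),
            np.asarray(d["level1_norm"]["scale"]),
            d["level1_norm"]["columns"],
        ),
        split_ratio=float(d["split_ratio"]),
        metadata=d.get("metadata", {}),
    )
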
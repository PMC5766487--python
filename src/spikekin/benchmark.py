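"""Fixed-design synthetic decoding benchmark.

Four stepping trials (three train, one test) of position-tuned units whose
rates span 10-80 Hz; FR-only, ISI-only and stacked decoders are trained on
the multiunit pool and scored on the held-out trial.  Used by the
acceptance suite to check the qualitative ordering stack <= FR < ISI.
"""
from __future__ import annotations

from .evaluation import ScoreReport
from .pipeline import PipelineConfig, run_pipeline

__all__ = ["run_decoding_benchmark", "benchmark_config"]


def benchmark_config(
    seed: int,
    trial_duration_s: float = 300.0,
    n_units: int = 4,
    max_epochs: int = 40,
    patience: int = 8,
    hidden: tuple[int, int] = (6, 6),
) -> PipelineConfig:
    return PipelineConfig(
        {
            "seed": int(seed),
            "variants": ["fr_multiunit", "isi_multiunit", "stack_multiunit"],
            "synth": {
                "n_trials": 4,
                "trial_duration_s": trial_duration_s,
                "n_units": n_units,
                "rate_range_hz": [10.0, 80.0],
            },
            "trials": {"train": [0, 1, 2], "model_selection": [], "test": [3]},
            "rnn": {
                "hidden": list(hidden),
                "max_epochs": max_epochs,
                "patience": patience,
            },
        }
    )


def run_decoding_benchmark(seed: int, **kwargs) -> dict[str, ScoreReport]:
    """Held-out scores per decoder on the fixed benchmark design.

    Returns ``{"fr": ScoreReport, "isi": ..., "stack": ...}``.
    """
    result = run_pipeline(benchmark_config(seed, **kwargs))
    rep = result["reports"]

    def as_report(d: dict) -> ScoreReport:
        return ScoreReport(nrms=d["nrms"], r2=d["r2"], n_points=d["n_points"])

    return {
        "fr": as_report(rep["fr_multiunit"]),
        "isi": as_report(rep["isi_multiunit"]),
        "stack": as_report(rep["stack_multiunit"]),
    }
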
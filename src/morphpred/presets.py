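"""Shared presets for simulation studies and reports.

``default_config`` is the full-size training schedule; the ``fast_*``
presets are the reduced schedules used by the repository's simulation
suites (null calibration, signal recovery, transferability,
contribution recovery) so that hundreds of refits stay cheap. The
reduced schedules shrink epochs and widths only — the pipeline structure
(binarize → pre-train → fine-tune → SVM) is identical.
"""

from __future__ import annotations

from .model import TwoStageConfig

__all__ = ["default_config", "fast_config", "tiny_config"]


def default_config(seed: int = 0) -> TwoStageConfig:
    """The full training schedule (150 → 64 → 32 → 8, 100/200 epochs)."""
    return TwoStageConfig(seed=seed)


def fast_config(seed: int = 0) -> TwoStageConfig:
    """Reduced schedule for simulation suites: 32→16→8 widths, 30/100 epochs."""
    return TwoStageConfig(
        layer_sizes=(32, 16, 8),
        pretrain_epochs=30,
        finetune_epochs=100,
        learning_rate=0.3,
        batch_size=16,
        seed=seed,
    )


def tiny_config(seed: int = 0) -> TwoStageConfig:
    """Minimal schedule for permutation-calibration sweeps (many refits)."""
    return TwoStageConfig(
        layer_sizes=(16, 4),
        pretrain_epochs=5,
        finetune_epochs=20,
        learning_rate=0.3,
        batch_size=32,
        seed=seed,
    )
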
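"""Channel-contribution analysis by one-at-a-time Rician-noise perturbation.

A trained patch-translation network is probed without retraining: one
input channel at a time is replaced by a Rician-noised copy of itself
(sigma = a fraction, default 10%, of that channel's within-mask mean),
the volume is re-translated, and the within-mask RMSE between the
perturbed and unperturbed outputs is recorded.  Averaged over repeats
and normalized across channels, these RMSEs quantify each channel's
relative contribution to the network output, support ranking channels,
and drive acquisition-subset selection (keep the smallest prefix of
the ranking that covers a desired share of the total contribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mrhnet import TrainedModel, translate_volume
from .phantom import add_rician_noise
from .volumes import MultiContrastVolume

__all__ = [
    "ContributionReport",
    "channel_contribution",
    "rank_and_cumulate",
    "select_subset",
    "group_contributions",
]


@dataclass
class ContributionReport:
    """Per-channel perturbation RMSEs and derived contribution shares."""

    rmse: np.ndarray                      # (C,) mean over repeats, target units
    contribution: np.ndarray              # (C,) normalized, sums to 1
    channel_labels: list[str]
    noise_fraction: float
    repeats: int
    seed: int
    rmse_per_repeat: np.ndarray | None = None   # (C, repeats)

    @property
    def n_channels(self) -> int:
        return self.rmse.size

    @property
    def ranking(self) -> np.ndarray:
        """Channel indices in descending contribution order (stable)."""
        # stable sort on negated values: ties broken by channel index
        return np.argsort(-self.contribution, kind="stable")

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative contribution along the ranking (ends at 1)."""
        return np.cumsum(self.contribution[self.ranking])

    def to_dataframe(self) -> pd.DataFrame:
        rank_of = np.empty(self.n_channels, dtype=int)
        rank_of[self.ranking] = np.arange(1, self.n_channels + 1)
        cum_of = np.empty(self.n_channels)
        cum_of[self.ranking] = self.cumulative
        return pd.DataFrame(
            {
                "channel": np.arange(self.n_channels),
                "label": self.channel_labels,
                "rmse": self.rmse,
                "contribution": self.contribution,
                "rank": rank_of,
                "cumulative": cum_of,
            }
        )


def channel_contribution(
    model: TrainedModel,
    volume: MultiContrastVolume,
    mask: np.ndarray,
    noise_fraction: float = 0.10,
    repeats: int = 10,
    seed: int = 0,
    axis: int = 0,
    aggregation: str = "overlap-average",
) -> ContributionReport:
    """Measure each channel's contribution to the network output.

    For channel ``j`` and repeat ``r`` (independent noise draws with
    deterministic per-(channel, repeat) seeds), channel ``j`` of the
    volume is Rician-noised, the volume is translated, and the
    within-mask RMSE against the unperturbed translation recorded.
    Per-channel RMSEs are averaged over repeats and normalized to sum
    to one.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if noise_fraction <= 0:
        raise ValueError("noise_fraction must be > 0")
    if volume.n_channels != model.spec.in_channels:
        raise ValueError(
            f"model expects {model.spec.in_channels} channels, "
            f"volume has {volume.n_channels}"
        )
    mask = np.asarray(mask, bool)
    baseline = translate_volume(model, volume, mask, axis, aggregation).data
    C = volume.n_channels
    rmse = np.zeros((C, repeats))
    root = np.random.SeedSequence(seed)
    for j in range(C):
        for r in range(repeats):
            sub = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(j, r))
            )
            data = volume.data.copy()
            data[..., j] = add_rician_noise(
                volume.data[..., j], noise_fraction, mask, sub
            )
            perturbed = translate_volume(
                model, volume.with_data(data), mask, axis, aggregation
            ).data
            rmse[j, r] = float(
                np.sqrt(np.mean((perturbed[mask] - baseline[mask]) ** 2))
            )
    mean_rmse = rmse.mean(axis=1)
    total = mean_rmse.sum()
    contribution = mean_rmse / total if total > 0 else np.full(C, 1.0 / C)
    return ContributionReport(
        rmse=mean_rmse,
        contribution=contribution,
        channel_labels=list(volume.channel_labels),
        noise_fraction=noise_fraction,
        repeats=repeats,
        seed=seed,
        rmse_per_repeat=rmse,
    )


def rank_and_cumulate(
    report: ContributionReport,
) -> tuple[np.ndarray, np.ndarray]:
    """Descending channel ranking and cumulative contribution fractions."""
    return report.ranking, report.cumulative


def select_subset(
    report: ContributionReport,
    coverage: float | None = None,
    top_k: int | None = None,
) -> np.ndarray:
    """Channels to keep: smallest ranking prefix covering ``coverage``,
    or exactly the ``top_k`` prefix.  Exactly one criterion may be given.

    The intended downstream use is retraining the network with the
    selected channels as its only inputs.
    """
    if (coverage is None) == (top_k is None):
        raise ValueError("give exactly one of coverage/top_k")
    ranking = report.ranking
    if top_k is not None:
        if not 1 <= top_k <= report.n_channels:
            raise ValueError(f"top_k must be in [1, {report.n_channels}]")
        return ranking[:top_k]
    if not 0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    n_keep = int(np.searchsorted(report.cumulative, coverage - 1e-12) + 1)
    return ranking[: min(n_keep, report.n_channels)]


def group_contributions(
    report: ContributionReport, groups: dict[str, str]
) -> pd.DataFrame:
    """Sum member-channel contributions over a channel-label -> group manifest.

    Useful for contrast-family summaries (e.g. T2W vs MT vs low/high-b
    diffusion, or pulsed vs oscillating gradient encodings).
    """
    missing = [lbl for lbl in report.channel_labels if lbl not in groups]
    if missing:
        raise ValueError(f"channels missing from group manifest: {missing}")
    df = report.to_dataframe()
    df["group"] = [groups[lbl] for lbl in report.channel_labels]
    agg = df.groupby("group", sort=False).agg(
        contribution=("contribution", "sum"),
        rmse=("rmse", "sum"),
        n_channels=("channel", "count"),
    )
    return agg.reset_index()
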
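"""End-to-end convenience layer: recordings -> channels -> features -> CV."""

from __future__ import annotations

from .classify import MetricsReport, PipelineConfig, run_cv
from .dynamics import ChannelConfig, build_channelset
from .features import DEFAULT_CONFIG, FeatureConfig, FeatureTable, extract_all
from .io import HandwritingSample
from .synthetic import Cohort

__all__ = ["extract_table", "evaluate_cohort"]


def extract_table(
    samples: dict[str, HandwritingSample],
    labels: dict[str, str] | None = None,
    channel_config: ChannelConfig = ChannelConfig(),
    feature_set: str = "tfst",
    feature_config: FeatureConfig = DEFAULT_CONFIG,
) -> FeatureTable:
    """Channel derivation + feature extraction over a set of recordings."""
    vectors = {}
    for rid, sample in samples.items():
        channels = build_channelset(sample, channel_config)
        vectors[rid] = extract_all(channels, feature_set=feature_set,
                                   config=feature_config,
                                   t=sample.time_seconds())
    if labels is None:
        labels = {rid: s.label for rid, s in samples.items()}
    return FeatureTable.from_vectors(vectors, labels)


def evaluate_cohort(
    cohort: Cohort,
    config: PipelineConfig = PipelineConfig(),
    channel_config: ChannelConfig = ChannelConfig(),
    feature_set: str = "tfst",
) -> MetricsReport:
    """Full pipeline on a synthetic cohort; returns the pooled CV report."""
    table = extract_table(cohort.samples, cohort.labels, channel_config,
                          feature_set)
    report, _ = run_cv(table, config=config)
    return report
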
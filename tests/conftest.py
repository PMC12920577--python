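"""Shared fixtures: small synthetic recordings and feature tensors."""

from __future__ import annotations

import numpy as np
import pytest

from graphecg.features import FeatureTensor
from graphecg.synth import NoiseSpec, SimConfig, synth_recording


@pytest.fixture(scope="session")
def clean_recording():
    """60 s, 2-lead, noise-free normal-rhythm recording with annotations."""
    cfg = SimConfig(fs=250.0, duration=60.0, n_leads=2, mean_hr=60.0,
                    hr_jitter_sd=0.0, noise=NoiseSpec(), seed=7)
    return synth_recording(cfg)


@pytest.fixture(scope="session")
def mixed_recording():
    """120 s, 2-lead recording with all four beat classes and mild noise."""
    cfg = SimConfig(fs=250.0, duration=120.0, n_leads=2, mean_hr=75.0,
                    hr_jitter_sd=0.02, class_probs=(0.4, 0.2, 0.2, 0.2),
                    class_persistence=0.9,
                    noise=NoiseSpec(baseline_amp=0.05, white_sd=0.01), seed=11)
    return synth_recording(cfg)


def make_cluster_features(n_per_class: int = 40, T: int = 4, n_leads: int = 2,
                          d_feat: int = 6, n_classes: int = 4, spread: float = 0.3,
                          seed: int = 0, n_patients: int = 8) -> FeatureTensor:
    """Small linearly separable feature tensor: one Gaussian cluster per class."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=2.0, size=(n_classes, d_feat))
    values, labels = [], []
    for c in range(n_classes):
        base = centers[c][None, None, None, :]
        noise = rng.normal(scale=spread, size=(n_per_class, T, n_leads, d_feat))
        values.append(base + noise)
        labels += [c] * n_per_class
    values = np.concatenate(values)
    labels = np.asarray(labels)
    order = rng.permutation(len(labels))
    patient_ids = np.array([f"p{i % n_patients}" for i in range(len(labels))])
    return FeatureTensor(values=values[order], mask=np.zeros_like(values[order]),
                         labels=labels[order],
                         feature_names=tuple(f"f{i}" for i in range(d_feat)),
                         patient_ids=patient_ids)


@pytest.fixture(scope="session")
def cluster_features():
    return make_cluster_features()
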
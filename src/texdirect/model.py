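"""Model/Results surface tying feature extraction to cross-validated SVM.

:class:`TextureClassificationModel` is built from labeled images plus the
experimental knobs (feature mode, DWT level, wavelet, Gabor bank, histogram
bins, SVM config); :meth:`~TextureClassificationModel.fit` runs the chosen
cross-validation protocol and returns a
:class:`TextureClassificationResults` carrying per-fold and pooled
CCR/sensitivity/specificity, the feature table, and a text ``summary()``.

:func:`compare_modes` runs the DWT-only, hybrid DWT-Gabor and Gabor-only
feature modes (at every requested DWT level) over identical folds, so any
metric difference is attributable to the features alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import PerformanceReport, SVMConfig, cross_validate
from .exceptions import ValidationError
from .features import DEFAULT_N_BINS, FeatureMode, feature_table
from .gabor import FilterBankConfig
from .synthetic import SyntheticConfig, generate_dataset
from .wavelet import WaveletSpec


class TextureClassificationModel:
    """Normal-vs-abnormal screening from directional texture descriptors.

    Parameters
    ----------
    images : sequence of 2-D float arrays in [0, 1]
    labels : sequence of {+1 (abnormal), -1 (normal)}
    ids : optional per-image identifiers
    mode : feature mode ('dwt', 'dwt_gabor' or 'gabor')
    level : DWT decomposition level (1 or 2; ignored for 'gabor')
    wavelet, bank, n_bins, svm : stage configurations (defaults: db4 with
        symmetric extension, the 12-filter unit-sigma bank, 256 bins,
        degree-2 polynomial SVM with C = 1)
    """

    def __init__(self, images, labels, ids=None, mode=FeatureMode.DWT_GABOR,
                 level: int | None = 1, wavelet: WaveletSpec | None = None,
                 bank: FilterBankConfig | None = None,
                 n_bins: int = DEFAULT_N_BINS, svm: SVMConfig | None = None):
        labels = np.asarray(labels)
        if len(images) != labels.size:
            raise ValidationError("images and labels must align")
        self.images = list(images)
        self.labels = labels
        self.ids = list(ids) if ids is not None else [f"img_{i:03d}" for i in range(labels.size)]
        self.mode = FeatureMode(mode)
        self.level = None if self.mode is FeatureMode.GABOR else level
        self.wavelet = wavelet or WaveletSpec.from_name()
        self.bank = bank or FilterBankConfig()
        self.n_bins = n_bins
        self.svm = svm or SVMConfig()
        self._features: pd.DataFrame | None = None

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig | None = None, **kwargs):
        """Build the model on a generated balanced dataset."""
        config = config or SyntheticConfig()
        images, labels, ids = generate_dataset(config)
        model = cls(images, labels, ids, **kwargs)
        model.synthetic_config = config
        return model

    @classmethod
    def from_directory(cls, root, **kwargs):
        """Build from ``root/normal`` and ``root/abnormal`` image folders."""
        from .io import load_labeled_directory

        images, labels, ids = load_labeled_directory(root)
        return cls(images, labels, ids, **kwargs)

    @property
    def features(self) -> pd.DataFrame:
        """Per-image feature table (computed lazily, cached)."""
        if self._features is None:
            self._features = feature_table(
                self.images, self.labels, self.ids, self.mode,
                level=self.level, wavelet=self.wavelet, bank=self.bank,
                n_bins=self.n_bins)
        return self._features

    def exog(self) -> np.ndarray:
        return self.features.drop(columns=["image_id", "label"]).to_numpy()

    def fit(self, protocol: str = "tenfold", seed: int = 0) -> "TextureClassificationResults":
        """Cross-validate the SVM over the extracted features."""
        report = cross_validate(self.exog(), self.labels, self.svm,
                                protocol=protocol, seed=seed)
        return TextureClassificationResults(self, report)


@dataclass
class TextureClassificationResults:
    """Cross-validated performance of one feature mode."""

    model: TextureClassificationModel
    report: PerformanceReport

    @property
    def per_fold(self) -> pd.DataFrame:
        return self.report.to_frame()

    @property
    def overall(self):
        """Metrics pooled over every held-out prediction."""
        return self.report.overall

    def mean_sd(self, name: str):
        return self.report.mean_sd(name)

    def summary(self) -> str:
        """Human-readable report in the mean +/- sd convention (percent)."""
        m = self.model
        lines = [
            "Texture screening cross-validation",
            "=" * 50,
            f"mode: {m.mode.value:<12} DWT level: {m.level}",
            f"wavelet: {m.wavelet.name} ({m.wavelet.boundary_mode})   "
            f"bank: {len(m.bank.frequencies)}x{len(m.bank.orientations)}   "
            f"bins: {m.n_bins}",
            f"SVM: poly degree {m.svm.degree}, C = {m.svm.C}",
            f"protocol: {self.report.protocol}   seed: {self.report.seed}   "
            f"n = {len(m.images)}",
            "-" * 50,
        ]
        for name, label in (("ccr", "CCR"), ("sensitivity", "sensitivity"),
                            ("specificity", "specificity")):
            mean, sd = self.mean_sd(name)
            pooled = getattr(self.overall, name)
            lines.append(f"{label:<12} {100 * mean:6.2f}% (+/- {sd:.2f})   "
                         f"pooled {100 * pooled:6.2f}%")
        return "\n".join(lines)

    def plot_folds(self, ax=None):
        """Bar chart of per-fold CCR (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.per_fold
        ax.bar(frame["fold"], frame["ccr"])
        ax.set_xlabel("fold")
        ax.set_ylabel("CCR")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{self.model.mode.value} per-fold CCR")
        return ax


def compare_modes(images, labels, ids=None, levels=(1, 2),
                  wavelet: WaveletSpec | None = None,
                  bank: FilterBankConfig | None = None,
                  n_bins: int = DEFAULT_N_BINS, svm: SVMConfig | None = None,
                  protocol: str = "tenfold", seed: int = 0) -> pd.DataFrame:
    """All three feature modes on identical folds; one row per (mode, level).

    Returns columns {mode, level, ccr_mean, ccr_sd, sensitivity_mean,
    sensitivity_sd, specificity_mean, specificity_sd} plus the pooled rates.
    Fold assignments depend only on (labels, seed), so they are shared across
    rows; this is asserted at run time.
    """
    runs = [(FeatureMode.DWT, lv) for lv in levels]
    runs += [(FeatureMode.DWT_GABOR, lv) for lv in levels]
    runs += [(FeatureMode.GABOR, None)]
    rows, assignments = [], None
    for mode, level in runs:
        model = TextureClassificationModel(
            images, labels, ids, mode=mode, level=level, wavelet=wavelet,
            bank=bank, n_bins=n_bins, svm=svm)
        res = model.fit(protocol=protocol, seed=seed)
        if assignments is None:
            assignments = res.report.fold_assignments
        elif not np.array_equal(assignments, res.report.fold_assignments):
            raise AssertionError("fold assignments diverged across modes")
        row = {"mode": mode.value, "level": level}
        for name in ("ccr", "sensitivity", "specificity"):
            mean, sd = res.mean_sd(name)
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
            row[f"{name}_overall"] = getattr(res.overall, name)
        rows.append(row)
    return pd.DataFrame(rows)
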
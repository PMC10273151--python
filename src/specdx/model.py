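"""Group-level invasion scoring model (statsmodels-style Model/Results).

:class:`InvasionClassifier` is constructed from data (directly from
labeled spectral groups, or via :meth:`InvasionClassifier.from_cohort`
which also performs the train/test split); :meth:`~InvasionClassifier.fit`
trains the 1D CNN and returns an :class:`InvasionClassifierResults`
carrying the fitted parameters, the training history, held-out
diagnostics (ROC, AUC, accuracy, Youden cutoffs) and a ``summary()``
table.  Prediction on new specimens and cohorts hangs off the results
object.

Labeling convention: a group is a positive example iff it is a *lesion*
group of a specimen whose paraffin diagnosis is IAC; perilesional groups
are always negative (they probe normal tissue).  By default the group's
three spectra are scored jointly as one 3-channel input (the diagnostic
unit is the measurement point, and admixed lesions are disambiguated by
cross-modality structure no single spectrum carries); a ``per_spectrum``
mode that scores each spectrum independently and averages the three
probabilities is also available.

The split replicating the original modeling design is *within-specimen*:
each specimen's 10 groups are allocated 9:1 to train and test.  Because
groups from one specimen share acquisition context, this split leaks
specimen identity into the test set and flatters the held-out metrics; a
``by_specimen`` mode is provided for honest generalization estimates.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .data import BinaryLabel, Site, Specimen, SpectralGroup
from .nn import NetConfig, SpectralCNN
from .preprocessing import group_to_block

__all__ = [
    "SplitSpec",
    "ModelConfig",
    "LabeledGroup",
    "label_group",
    "split_dataset",
    "InvasionClassifier",
    "InvasionClassifierResults",
    "train_classifier",
    "predict_group_probability",
]


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Train/test partition specification.

    ``within_specimen`` allocates each specimen's 10 groups 9:1 (the
    original modeling design); ``by_specimen`` assigns whole specimens.
    """

    mode: str = "within_specimen"
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("within_specimen", "by_specimen"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclasses.dataclass
class ModelConfig:
    """Architecture and optimisation settings of the scoring CNN."""

    conv_channels: tuple[int, int] = (16, 32)
    kernel_width: int = 9
    pool: int = 4
    dense_width: int = 64
    learning_rate: float = 3e-3
    epochs: int = 40
    batch_size: int = 32
    #: ``stacked`` (default): one 3-channel input per group, scoring the
    #: group's spectra jointly so cross-modality structure is visible;
    #: ``per_spectrum``: score the 3 spectra independently and average.
    input_mode: str = "stacked"
    seed: int = 0

    def net_config(self) -> NetConfig:
        in_ch = 1 if self.input_mode == "per_spectrum" else 3
        return NetConfig(
            in_channels=in_ch,
            conv_channels=tuple(self.conv_channels),
            kernel_width=self.kernel_width,
            pool=self.pool,
            dense_width=self.dense_width,
            learning_rate=self.learning_rate,
        )


@dataclasses.dataclass
class LabeledGroup:
    """One spectral group with its specimen context and binary label."""

    specimen_id: str
    truth_class: str
    site: Site
    point_index: int
    label: int  # 1 = invasive adenocarcinoma (lesion group of an IAC specimen)
    group: SpectralGroup


def label_group(specimen: Specimen, group: SpectralGroup) -> int:
    return int(
        group.site is Site.LESION and specimen.binary_label is BinaryLabel.IAC
    )


def _records(specimen: Specimen) -> list[LabeledGroup]:
    return [
        LabeledGroup(
            specimen.specimen_id,
            specimen.truth_class.value,
            g.site,
            g.point_index,
            label_group(specimen, g),
            g,
        )
        for g in specimen.groups
    ]


def split_dataset(
    cohort: Sequence[Specimen], spec: SplitSpec = SplitSpec()
) -> tuple[list[LabeledGroup], list[LabeledGroup]]:
    """Partition a cohort's groups into disjoint, exhaustive train/test sets.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    train: list[LabeledGroup] = []
    test: list[LabeledGroup] = []
    if spec.mode == "within_specimen":
        for specimen in cohort:
            recs = _records(specimen)
            n = len(recs)
            n_test = int(round((1.0 - spec.train_fraction) * n))
            if n_test < 1 or n_test >= n:
                raise ValueError(
                    f"train_fraction {spec.train_fraction} incompatible with "
                    f"{n} groups per specimen"
                )
            order = rng.permutation(n)
            test.extend(recs[i] for i in order[:n_test])
            train.extend(recs[i] for i in order[n_test:])
    else:  # by_specimen, stratified on the specimen's binary label
        n = len(cohort)
        n_test = int(round((1.0 - spec.train_fraction) * n))
        if n_test < 1 or n_test >= n:
            raise ValueError(
                f"train_fraction {spec.train_fraction} incompatible with "
                f"{n} specimens"
            )
        test_idx: list[int] = []
        for label in (BinaryLabel.IAC, BinaryLabel.NON_IAC):
            stratum = [i for i, s in enumerate(cohort) if s.binary_label is label]
            k = max(1, int(round((1.0 - spec.train_fraction) * len(stratum))))
            order = rng.permutation(len(stratum))
            test_idx.extend(stratum[i] for i in order[:k])
        for i in range(n):
            (test if i in set(test_idx) else train).extend(_records(cohort[i]))
    return train, test


def _design_matrix(
    records: Sequence[LabeledGroup], input_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Blocks -> network inputs.  per_spectrum: (3n, 1, L); stacked: (n, 3, L)."""
    blocks = np.stack([group_to_block(r.group) for r in records])  # (n, 3, L)
    labels = np.array([r.label for r in records], dtype=np.float32)
    if input_mode == "per_spectrum":
        n, c, l = blocks.shape
        x = blocks.reshape(n * c, 1, l)
        y = np.repeat(labels, c)
        return x.astype(np.float32), y
    return blocks.astype(np.float32), labels


class InvasionClassifier:
    """IAC vs non-IAC spectral-group scoring model.

    Parameters
    ----------
    train_records, test_records
        Labeled groups; the test set may be empty (fit-only use).
    config
        Architecture/optimisation settings; ``config.seed`` controls
        initialisation and batch order unless ``fit(seed=...)`` overrides.
    """

    def __init__(
        self,
        train_records: Sequence[LabeledGroup],
        test_records: Sequence[LabeledGroup] = (),
        config: ModelConfig | None = None,
    ) -> None:
        self.config = config or ModelConfig()
        self.train_records = list(train_records)
        self.test_records = list(test_records)
        labels = {r.label for r in self.train_records}
        if len(labels) < 2:
            raise ValueError(
                "training set must contain both positive and negative groups"
            )

    @classmethod
    def from_cohort(
        cls,
        cohort: Sequence[Specimen],
        split: SplitSpec = SplitSpec(),
        config: ModelConfig | None = None,
    ) -> "InvasionClassifier":
        train, test = split_dataset(cohort, split)
        return cls(train, test, config)

    def fit(self, seed: int | None = None) -> "InvasionClassifierResults":
        seed = self.config.seed if seed is None else seed
        net = SpectralCNN(self.config.net_config(), seed=seed)
        x, y = _design_matrix(self.train_records, self.config.input_mode)
        rng = np.random.default_rng(seed + 1)
        history = net.fit(
            x, y, epochs=self.config.epochs, batch_size=self.config.batch_size, rng=rng
        )
        return InvasionClassifierResults(self, net, history, seed)


class InvasionClassifierResults:
    """Fitted scoring model plus held-out diagnostics."""

    def __init__(
        self,
        model: InvasionClassifier,
        net: SpectralCNN,
        history: list[float],
        seed: int,
    ) -> None:
        self.model = model
        self.net = net
        self.history = history
        self.seed = seed
        self._test_probs: np.ndarray | None = None

    # -- prediction ---------------------------------------------------------

    def predict_records(self, records: Sequence[LabeledGroup]) -> np.ndarray:
        """Group-level invasion probabilities, in record order."""
        if not records:
            return np.empty(0)
        x, _ = _design_matrix(records, self.model.config.input_mode)
        p = self.net.predict_proba(x)
        if self.model.config.input_mode == "per_spectrum":
            p = p.reshape(len(records), 3).mean(axis=1)
        return p

    def predict_group_probability(self, group: SpectralGroup) -> float:
        rec = LabeledGroup("?", "?", group.site, group.point_index, 0, group)
        return float(self.predict_records([rec])[0])

    def score_cohort(self, cohort: Sequence[Specimen]) -> pd.DataFrame:
        """Per-group probabilities for a cohort, one row per spectral group."""
        rows = []
        for specimen in cohort:
            recs = _records(specimen)
            probs = self.predict_records(recs)
            for r, p in zip(recs, probs):
                rows.append(
                    {
                        "specimen_id": r.specimen_id,
                        "truth_class": r.truth_class,
                        "site": r.site.value,
                        "point_index": r.point_index,
                        "label": r.label,
                        "probability": float(p),
                    }
                )
        return pd.DataFrame(rows)

    # -- held-out diagnostics -----------------------------------------------

    @property
    def test_labels(self) -> np.ndarray:
        return np.array([r.label for r in self.model.test_records])

    @property
    def test_probabilities(self) -> np.ndarray:
        if self._test_probs is None:
            self._test_probs = self.predict_records(self.model.test_records)
        return self._test_probs

    def roc(self) -> evaluation.ROCCurve:
        return evaluation.roc_curve(self.test_probabilities, self.test_labels)

    @property
    def auc(self) -> float:
        return evaluation.auc(self.roc())

    def accuracy(self, cutoff: float = 0.5) -> float:
        """Held-out group accuracy (fraction) at a probability cutoff."""
        calls = (self.test_probabilities > cutoff).astype(int)
        return float(np.mean(calls == self.test_labels))

    def youden_table(self, top: int = 5) -> pd.DataFrame:
        return evaluation.youden_cutoffs(self.roc()).head(top)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.model.config
        buf.write("Invasion scoring model (1D CNN)\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"train groups:        {len(self.model.train_records)}\n")
        buf.write(f"test groups:         {len(self.model.test_records)}\n")
        buf.write(
            f"architecture:        conv{cfg.conv_channels} k={cfg.kernel_width} "
            f"pool={cfg.pool} dense={cfg.dense_width} ({cfg.input_mode})\n"
        )
        buf.write(
            f"training:            {cfg.epochs} epochs, batch {cfg.batch_size}, "
            f"lr {cfg.learning_rate}, seed {self.seed}\n"
        )
        buf.write(f"final train loss:    {self.history[-1]:.4f}\n")
        if self.model.test_records:
            buf.write(f"held-out AUC:        {self.auc:.3f}\n")
            buf.write(f"held-out acc @0.5:   {100 * self.accuracy(0.5):.2f}%\n")
            top = self.youden_table(2)
            for _, row in top.iterrows():
                buf.write(
                    f"cutoff {row.cutoff:.3f}:        sens {row.sensitivity:.3f}, "
                    f"spec {row.specificity:.3f}, J {row.youden_j:.3f}\n"
                )
        return buf.getvalue()


def train_classifier(
    train_records: Sequence[LabeledGroup],
    config: ModelConfig | None = None,
    seed: int | None = None,
) -> InvasionClassifierResults:
    """Functional wrapper: fit the scoring CNN on labeled groups."""
    return InvasionClassifier(train_records, (), config).fit(seed)


def predict_group_probability(
    results: InvasionClassifierResults, group: SpectralGroup
) -> float:
    return results.predict_group_probability(group)
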
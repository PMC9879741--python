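"""Desk-scale simulation studies.

These run the full method — cohort simulation, preprocessing, network
training, prediction, centerline measurement, cohort statistics — in memory
at matrix sizes that train in about a minute on one CPU: a 48 x 32 localizer,
a 64 x 48 x 32 coronal target on a 384 x 480 x 192 mm grid, and a depth-3
network.  The population and mis-centering conditions are the generator
defaults; only the matrix sizes are scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .centerline import CenterlineConfig, measure_centerlines
from .core import Grid3D
from .metrics import PositioningResults, evaluate_cohort
from .phantom import sample_population, simulate_case
from .preprocess import PreprocessConfig, make_training_pair
from .reconstructor import LocalizerToVolumeModel, ModelConfig, TrainConfig

__all__ = ["RecoveryStudyResult", "desk_scale_recovery_study"]


@dataclass
class RecoveryStudyResult:
    """Outcome of one train/test recovery study."""

    results: PositioningResults
    loss_history: List[float]
    n_train: int
    n_test: int
    seed: int

    @property
    def bcap(self) -> np.ndarray:
        return np.array([e.bcap for e in self.results.errors])

    @property
    def bcmp(self) -> np.ndarray:
        return np.array([e.bcmp for e in self.results.errors])

    @property
    def lcap(self) -> np.ndarray:
        return np.array([e.lcap for e in self.results.errors
                         if e.lcap is not None])

    @property
    def mean_abs_bcap(self) -> float:
        return float(np.mean(np.abs(self.bcap)))


def desk_scale_recovery_study(
    seed: int,
    n_train: int = 200,
    n_test: int = 50,
    epochs: int = 20,
    learning_rate: float = 3e-3,
    base_channels: int = 8,
    depth: int = 3,
    centerline_config: CenterlineConfig = CenterlineConfig(),
) -> RecoveryStudyResult:
    """Train on ``n_train`` simulated phantoms, evaluate positioning errors
    on ``n_test`` held-out phantoms; everything derives from ``seed``."""
    grid = Grid3D.centered((96, 96, 32), (4.0, 5.0, 6.0))
    pconf = PreprocessConfig(localizer_shape=(48, 32),
                             volume_shape=(64, 48, 32))
    specs = sample_population(n_train + n_test, seed=seed)
    pairs, cases = [], []
    for i, spec in enumerate(specs):
        case = simulate_case(spec, grid, case_id=f"case{i:04d}")
        pairs.append(make_training_pair(case.localizer, case.volume, pconf,
                                        case_id=case.case_id))
        cases.append(case)

    model = LocalizerToVolumeModel(
        ModelConfig(depth=depth, base_channels=base_channels,
                    output_ap_bins=pconf.volume_shape[0],
                    input_shape=pconf.localizer_shape),
        seed=seed)
    fit = model.fit(pairs[:n_train],
                    TrainConfig(epochs=epochs, seed=seed,
                                learning_rate=learning_rate))

    report_pairs, case_ids, body_sizes = [], [], []
    for pair, case in zip(pairs[n_train:], cases[n_train:]):
        rep_gt = measure_centerlines(case.volume, centerline_config,
                                     source="ground_truth")
        pred = model.predict_volume(pair.localizer_in, pair.crop_record)
        rep_dl = measure_centerlines(pred, centerline_config,
                                     source="predicted")
        report_pairs.append((rep_gt, rep_dl))
        case_ids.append(case.case_id)
        body_sizes.append(float(np.sqrt(
            4.0 * case.spec.body_semi_axis_ap * case.spec.body_semi_axis_lat)))

    results = evaluate_cohort(report_pairs, isocenter_y=grid.isocenter_y,
                              case_ids=case_ids, body_sizes=body_sizes,
                              seed=seed)
    return RecoveryStudyResult(results=results, loss_history=fit.loss_history,
                               n_train=n_train, n_test=len(report_pairs),
                               seed=seed)
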
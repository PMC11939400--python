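"""Relative gene expression by the 2^-ddCq method.

For each sample i with target-gene quantification cycle ``cq_target`` and
reference-gene cycle ``cq_reference`` (GAPDH-style normaliser):

    dCq_i  = cq_target_i - cq_reference_i
    ddCq_i = dCq_i - dCq_cal
    RE_i   = 2 ** (-ddCq_i)

where ``dCq_cal`` is either one explicit calibrator sample's dCq or the
arithmetic mean dCq of a calibrator group (default: the winter-solstice
group, so seasonal profiles read as fold change versus winter).  All RE
ratios between samples are invariant to the calibrator choice, so every
downstream statistic is calibrator-free; the calibrator only sets the
unit.  No amplification-efficiency (Pfaffl) correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

__all__ = ["CalibratorSpec", "DeltaDeltaCq", "delta_delta_cq"]


@dataclass
class CalibratorSpec:
    """Calibrator choice: exactly one of ``group`` or ``sample_id``.

    group : season label whose mean dCq calibrates (mode ``group_mean``)
    sample_id : single calibrator sample (mode ``explicit_sample``)
    """

    group: str | None = "winter"
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if (self.group is None) == (self.sample_id is None):
            raise ValueError("specify exactly one of group= or sample_id=")

    @property
    def mode(self) -> str:
        return "group_mean" if self.group is not None else "explicit_sample"


class DeltaDeltaCq(BaseEstimator):
    """2^-ddCq transformer over a qPCR sample table.

    ``fit`` resolves the calibrator dCq from the table; ``transform``
    appends a ``relative_expression`` column.  Samples with non-finite Cq
    are flagged (``qc_excluded``), excluded from the calibrator mean, and
    get NaN expression with a logged count.

    Parameters
    ----------
    calibrator : CalibratorSpec | str, default "winter"
        A season name is shorthand for group-mean calibration on that
        season.

    Attributes
    ----------
    calibrator_dcq_ : float
        The resolved calibrator dCq.
    """

    def __init__(self, calibrator: CalibratorSpec | str = "winter"):
        self.calibrator = calibrator

    def _spec(self) -> CalibratorSpec:
        if isinstance(self.calibrator, CalibratorSpec):
            return self.calibrator
        return CalibratorSpec(group=self.calibrator)

    def fit(self, samples: pd.DataFrame, y=None):
        spec = self._spec()
        dcq = samples["cq_target"] - samples["cq_reference"]
        ok = np.isfinite(dcq)
        if spec.mode == "group_mean":
            sel = (samples["season"] == spec.group) & ok
            if not sel.any():
                raise ValueError(f"empty calibrator group {spec.group!r}")
            cal = float(dcq[sel].mean())
        else:
            sel = (samples["participant_id"] == spec.sample_id) & ok
            if sel.sum() != 1:
                raise ValueError(
                    f"calibrator sample {spec.sample_id!r} matches {int(sel.sum())} rows")
            cal = float(dcq[sel].iloc[0])
        self.calibrator_dcq_ = cal
        return self

    def transform(self, samples: pd.DataFrame) -> pd.DataFrame:
        out = samples.copy()
        dcq = out["cq_target"] - out["cq_reference"]
        ok = np.isfinite(dcq)
        n_bad = int((~ok).sum())
        if n_bad:
            log.warning("%d sample(s) with non-finite Cq excluded", n_bad)
        ddcq = dcq - self.calibrator_dcq_
        re = np.power(2.0, -ddcq)
        re[~ok] = np.nan
        out["delta_cq"] = dcq
        out["delta_delta_cq"] = ddcq
        out["relative_expression"] = re
        out["qc_excluded"] = ~ok
        return out

    def fit_transform(self, samples: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(samples).transform(samples)


def delta_delta_cq(samples: pd.DataFrame,
                   calibrator: CalibratorSpec | str = "winter") -> pd.DataFrame:
    """Fill ``relative_expression`` on a qPCR table; see :class:`DeltaDeltaCq`."""
    return DeltaDeltaCq(calibrator=calibrator).fit_transform(samples)
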
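"""Pseudo individual-patient PFS data emulating the source trial's two arms.

No patient-level data from the trial are available, so survival fitting is
exercised on synthetic records: Weibull event times drawn by inverse
transform per arm (defaults calibrated to the trial medians of 13.1 and 4.6
months), administratively censored at a fixed follow-up time.  The module
also provides the Kaplan-Meier product-limit estimator so the full
generate -> estimate -> fit loop closes without external inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import WeibullParams, weibull_from_median

__all__ = ["PseudoIPD", "KMCurve", "generate_ipd", "km_estimate"]

DEFAULT_N_PER_ARM = 500
DEFAULT_CENSOR_MONTHS = 24.0


@dataclass(frozen=True)
class PseudoIPD:
    """Synthetic patient records plus the metadata to regenerate them."""

    data: pd.DataFrame  # columns: id, arm, time_months, event
    true_params: dict[str, WeibullParams]
    censor_time: float
    seed: int

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.data["arm"].unique())

    def arm_frame(self, arm: str) -> pd.DataFrame:
        sub = self.data[self.data["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no records for arm {arm!r}")
        return sub

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray

    @property
    def has_events(self) -> bool:
        return len(self.times) > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_ipd(
    params_by_arm: dict[str, WeibullParams] | None = None,
    n_per_arm: int = DEFAULT_N_PER_ARM,
    censor_time: float = DEFAULT_CENSOR_MONTHS,
    seed: int = 0,
) -> PseudoIPD:
    """Draw Weibull PFS times per arm with administrative censoring.

    Times are inverse-transform draws t = scale * (-ln U)^(1/shape); any
    time reaching ``censor_time`` is recorded as censored there.  The same
    seed always regenerates the identical table.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    if params_by_arm is None:
        params_by_arm = {
            "erlotinib": weibull_from_median(13.1),
            "cg": weibull_from_median(4.6),
        }
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 0
    for arm, wp in params_by_arm.items():
        u = rng.uniform(size=n_per_arm)
        t = wp.scale * (-np.log(u)) ** (1.0 / wp.shape)
        event = (t < censor_time).astype(int)
        time = np.minimum(t, censor_time)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(next_id, next_id + n_per_arm),
                    "arm": arm,
                    "time_months": time,
                    "event": event,
                }
            )
        )
        next_id += n_per_arm
    return PseudoIPD(
        data=pd.concat(frames, ignore_index=True),
        true_params=dict(params_by_arm),
        censor_time=censor_time,
        seed=seed,
    )


def km_estimate(ipd: PseudoIPD | pd.DataFrame, arm: str | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one arm.

    At each distinct event time, S is multiplied by (1 - d/n) where d is
    the number of events and n the number still at risk; censored times
    only shrink the risk set.  A dataset with no events yields an empty
    (flat-1.0) curve, detectable via ``has_events``.
    """
    if isinstance(ipd, PseudoIPD):
        if arm is None:
            raise ValueError("arm is required when passing a PseudoIPD")
        frame = ipd.arm_frame(arm)
    else:
        frame = ipd if arm is None else ipd[ipd["arm"] == arm]
    if len(frame) == 0:
        raise ValueError("no records to estimate from")

    time = frame["time_months"].to_numpy(dtype=float)
    event = frame["event"].to_numpy(dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    out_t, out_s, out_n, out_d = [], [], [], []
    s = 1.0
    n_total = len(time)
    i = 0
    while i < n_total:
        t = time[i]
        j = i
        d = 0
        while j < n_total and time[j] == t:
            d += event[j]
            j += 1
        n_risk = n_total - i
        if d > 0:
            s *= 1.0 - d / n_risk
            out_t.append(t)
            out_s.append(s)
            out_n.append(n_risk)
            out_d.append(d)
        i = j
    return KMCurve(
        times=np.asarray(out_t, dtype=float),
        survival=np.asarray(out_s, dtype=float),
        n_risk=np.asarray(out_n, dtype=int),
        n_events=np.asarray(out_d, dtype=int),
    )
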
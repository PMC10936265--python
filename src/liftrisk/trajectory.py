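"""Time-series container for lifting motions and its CSV round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Sampled states, controls and constraint forces over the three phases.

    ``phase`` labels each sample 1/2/3; constraint forces are stored per
    named constraint (columns ``lam_<name>_<k>``).  ``extras`` carries
    scalar per-sample channels (L5/S1 moment, lumbar flexion angle, exo
    control, ...).
    """

    time: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray | None = None
    tau: np.ndarray | None = None
    phase: np.ndarray | None = None
    lam: dict[str, np.ndarray] = field(default_factory=dict)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        n = self.time.shape[0]
        if self.q.shape[0] != n or self.qd.shape != self.q.shape:
            raise ValueError("inconsistent trajectory array shapes")

    @property
    def nq(self) -> int:
        return self.q.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time": self.time}
        for k in range(self.nq):
            cols[f"q_{k}"] = self.q[:, k]
        for k in range(self.nq):
            cols[f"qd_{k}"] = self.qd[:, k]
        if self.qdd is not None:
            for k in range(self.nq):
                cols[f"qdd_{k}"] = self.qdd[:, k]
        if self.tau is not None:
            for k in range(self.nq):
                cols[f"tau_{k}"] = self.tau[:, k]
        if self.phase is not None:
            cols["phase"] = self.phase
        for name, arr in self.lam.items():
            for k in range(arr.shape[1]):
                cols[f"lam_{name}_{k}"] = arr[:, k]
        for name, arr in self.extras.items():
            cols[name] = arr
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        nq = sum(1 for c in df.columns if c.startswith("q_") and not c.startswith("qd"))
        q = df[[f"q_{k}" for k in range(nq)]].to_numpy()
        qd = df[[f"qd_{k}" for k in range(nq)]].to_numpy()
        qdd = None
        if f"qdd_0" in df.columns:
            qdd = df[[f"qdd_{k}" for k in range(nq)]].to_numpy()
        tau = None
        if f"tau_0" in df.columns:
            tau = df[[f"tau_{k}" for k in range(nq)]].to_numpy()
        phase = df["phase"].to_numpy() if "phase" in df.columns else None
        lam: dict[str, np.ndarray] = {}
        lam_cols = [c for c in df.columns if c.startswith("lam_")]
        names = sorted({c.rsplit("_", 1)[0][4:] for c in lam_cols})
        for name in names:
            ks = sorted(
                int(c.rsplit("_", 1)[1]) for c in lam_cols if c.rsplit("_", 1)[0][4:] == name
            )
            lam[name] = df[[f"lam_{name}_{k}" for k in ks]].to_numpy()
        known = {"time", "phase"} | set(
            f"{p}_{k}" for p in ("q", "qd", "qdd", "tau") for k in range(nq)
        ) | set(lam_cols)
        extras = {c: df[c].to_numpy() for c in df.columns if c not in known}
        return cls(
            time=df["time"].to_numpy(),
            q=q,
            qd=qd,
            qdd=qdd,
            tau=tau,
            phase=phase,
            lam=lam,
            extras=extras,
        )
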
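"""Serialization of the package's tables and trial containers.

TrialSet round-trips through HDF5 (group with data/fs/t0_index/windows) or a
commented CSV (one row per trial, metadata in '#key=value' header lines).
Injection records, MP atom lists and burst-event tables are plain CSVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mp import AtomRecord
from .synthetic import GaborParams, InjectionRecord, TrialSet


def save_trialset_h5(path, trialset: TrialSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trialset.data)
        f.attrs["fs"] = trialset.fs
        f.attrs["t0_index"] = trialset.t0_index
        f.attrs["baseline_window"] = trialset.baseline_window
        f.attrs["stim_window"] = trialset.stim_window


def load_trialset_h5(path) -> TrialSet:
    import h5py

    with h5py.File(path, "r") as f:
        return TrialSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            t0_index=int(f.attrs["t0_index"]),
            baseline_window=tuple(f.attrs["baseline_window"]),
            stim_window=tuple(f.attrs["stim_window"]),
        )


def save_trialset_csv(path, trialset: TrialSet) -> None:
    with open(path, "w") as f:
        f.write(f"#fs={trialset.fs}\n#t0_index={trialset.t0_index}\n")
        f.write(f"#baseline_window={trialset.baseline_window[0]},{trialset.baseline_window[1]}\n")
        f.write(f"#stim_window={trialset.stim_window[0]},{trialset.stim_window[1]}\n")
        np.savetxt(f, trialset.data, delimiter=",")


def load_trialset_csv(path) -> TrialSet:
    meta = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, val = line[1:].strip().split("=", 1)
            meta[key] = val
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        data = np.loadtxt(f, delimiter=",", ndmin=2)
    kwargs = {}
    for key in ("baseline_window", "stim_window"):
        if key in meta:
            a, b = meta[key].split(",")
            kwargs[key] = (float(a), float(b))
    return TrialSet(data=data, fs=float(meta["fs"]), t0_index=int(meta["t0_index"]), **kwargs)


def injections_to_frame(record: InjectionRecord) -> pd.DataFrame:
    rows = [
        {
            "trial": trial,
            "scale_s": a.scale_s,
            "shift_u": a.shift_u,
            "freq_xi": a.freq_xi,
            "phase": a.phase,
            "amplitude": a.amplitude,
        }
        for trial, a in record.all_bursts()
    ]
    return pd.DataFrame(rows, columns=["trial", "scale_s", "shift_u", "freq_xi", "phase", "amplitude"])


def injections_from_frame(df: pd.DataFrame, n_trials: int | None = None) -> InjectionRecord:
    n = int(n_trials if n_trials is not None else (df["trial"].max() + 1 if len(df) else 0))
    bursts: list[list[GaborParams]] = [[] for _ in range(n)]
    for _, row in df.iterrows():
        bursts[int(row["trial"])].append(
            GaborParams(row["scale_s"], row["shift_u"], row["freq_xi"], row["phase"], row["amplitude"])
        )
    return InjectionRecord(bursts)


def atoms_to_frame(decompositions: list[list[AtomRecord]]) -> pd.DataFrame:
    rows = []
    for trial, recs in enumerate(decompositions):
        for r in recs:
            rows.append(
                {
                    "trial": trial,
                    "iteration": r.iteration_index,
                    "scale_s": r.atom.scale_s,
                    "shift_u": r.atom.shift_u,
                    "freq_xi": r.atom.freq_xi,
                    "phase": r.atom.phase,
                    "coefficient": r.coefficient,
                    "residual_energy_after": r.residual_energy_after,
                }
            )
    cols = ["trial", "iteration", "scale_s", "shift_u", "freq_xi", "phase", "coefficient", "residual_energy_after"]
    return pd.DataFrame(rows, columns=cols)


def atoms_from_frame(df: pd.DataFrame) -> list[list[AtomRecord]]:
    n = int(df["trial"].max() + 1) if len(df) else 0
    out: list[list[AtomRecord]] = [[] for _ in range(n)]
    for _, row in df.iterrows():
        out[int(row["trial"])].append(
            AtomRecord(
                atom=GaborParams(row["scale_s"], row["shift_u"], row["freq_xi"], row["phase"]),
                coefficient=row["coefficient"],
                iteration_index=int(row["iteration"]),
                residual_energy_after=row["residual_energy_after"],
            )
        )
    return out
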
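"""Session container: trials x channels of LFP/MU/eye traces with metadata.

A :class:`SessionData` holds one recording session laid out the way the
downstream analyses expect it: per-trial LFP and multi-unit (MU) envelope
matrices at the decimated rate, spike-time lists, binocular-averaged eye
position and pupil traces at the eye-tracker rate, a condition table, and
the electrode-grid geometry needed for spike-field pair selection.

Sessions round-trip through an HDF5 container
(``/trials/<k>/{lfp,mu,spikes,eye,pupil}`` plus a ``/meta`` condition table)
and the condition table exports to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


@dataclass
class SessionData:
    """One session of (possibly synthetic) V1 recordings.

    Attributes
    ----------
    fs_lfp : float
        Sampling rate of the LFP/MU traces in Hz (nominally 24414.0625/24).
    fs_eye : float
        Sampling rate of eye-position and pupil traces in Hz.
    stim_onset : float
        Stimulus onset time in seconds from trial start (= baseline length).
    stim_duration : float
        Stimulus presentation length in seconds.
    lfp, mu : ndarray, shape (n_trials, n_channels, n_samples)
        LFP traces and nonnegative MU envelopes.
    spikes : list of list of ndarray
        ``spikes[trial][channel]`` spike times in seconds from trial start.
    eye : ndarray, shape (n_trials, 2, n_eye_samples)
        Horizontal/vertical gaze position in degrees.
    pupil : ndarray, shape (n_trials, n_eye_samples)
        Pupil size in (arbitrary, possibly negative) tracker units.
    conditions : DataFrame
        One row per trial with at least ``trial_id`` and ``label`` columns.
    channel_positions : ndarray, shape (n_channels, 2)
        Grid coordinates in units of the inter-electrode spacing.
    channel_depths : ndarray, shape (n_channels,)
        Electrode depth class (arrays with two fixed shank lengths).
    """

    fs_lfp: float
    fs_eye: float
    stim_onset: float
    stim_duration: float
    lfp: np.ndarray
    mu: np.ndarray
    spikes: list
    eye: np.ndarray
    pupil: np.ndarray
    conditions: pd.DataFrame
    channel_positions: np.ndarray
    channel_depths: np.ndarray
    grid_spacing: float = 1.0
    session_id: str = "synthetic"
    monkey: str = "S"
    extras: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def trial_duration(self) -> float:
        return self.lfp.shape[2] / self.fs_lfp

    def trials_for(self, label: str) -> np.ndarray:
        """Trial indices carrying a given condition label."""
        mask = self.conditions["label"].to_numpy() == label
        return np.flatnonzero(mask)

    @property
    def labels(self) -> list:
        seen: dict = {}
        for lab in self.conditions["label"]:
            seen.setdefault(lab, None)
        return list(seen)


def save_session(sess: SessionData, path) -> None:
    """Write a session to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["fs_lfp"] = sess.fs_lfp
        f.attrs["fs_eye"] = sess.fs_eye
        f.attrs["stim_onset"] = sess.stim_onset
        f.attrs["stim_duration"] = sess.stim_duration
        f.attrs["grid_spacing"] = sess.grid_spacing
        f.attrs["session_id"] = sess.session_id
        f.attrs["monkey"] = sess.monkey
        trials = f.create_group("trials")
        for k in range(sess.n_trials):
            g = trials.create_group(str(k))
            g.create_dataset("lfp", data=sess.lfp[k])
            g.create_dataset("mu", data=sess.mu[k])
            g.create_dataset("eye", data=sess.eye[k])
            g.create_dataset("pupil", data=sess.pupil[k])
            sp = g.create_group("spikes")
            for c, st in enumerate(sess.spikes[k]):
                sp.create_dataset(str(c), data=np.asarray(st, dtype=float))
        meta = f.create_group("meta")
        meta.create_dataset(
            "trial_id", data=sess.conditions["trial_id"].to_numpy(dtype=np.int64)
        )
        meta.create_dataset(
            "label",
            data=np.array(
                [str(x) for x in sess.conditions["label"]], dtype=h5py.string_dtype()
            ),
        )
        meta.create_dataset("channel_positions", data=sess.channel_positions)
        meta.create_dataset("channel_depths", data=sess.channel_depths)


def load_session(path) -> SessionData:
    """Read a session previously written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        keys = sorted(f["trials"], key=int)
        lfp = np.stack([f["trials"][k]["lfp"][()] for k in keys])
        mu = np.stack([f["trials"][k]["mu"][()] for k in keys])
        eye = np.stack([f["trials"][k]["eye"][()] for k in keys])
        pupil = np.stack([f["trials"][k]["pupil"][()] for k in keys])
        spikes = []
        for k in keys:
            g = f["trials"][k]["spikes"]
            spikes.append([g[str(c)][()] for c in range(len(g))])
        conditions = pd.DataFrame(
            {
                "trial_id": f["meta"]["trial_id"][()],
                "label": [s.decode() for s in f["meta"]["label"][()]],
            }
        )
        return SessionData(
            fs_lfp=float(f.attrs["fs_lfp"]),
            fs_eye=float(f.attrs["fs_eye"]),
            stim_onset=float(f.attrs["stim_onset"]),
            stim_duration=float(f.attrs["stim_duration"]),
            lfp=lfp,
            mu=mu,
            spikes=spikes,
            eye=eye,
            pupil=pupil,
            conditions=conditions,
            channel_positions=f["meta"]["channel_positions"][()],
            channel_depths=f["meta"]["channel_depths"][()],
            grid_spacing=float(f.attrs["grid_spacing"]),
            session_id=str(f.attrs["session_id"]),
            monkey=str(f.attrs["monkey"]),
        )
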
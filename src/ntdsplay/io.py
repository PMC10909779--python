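"""Plain-text readers/writers for ensembles, windows, traces, and weights.

Formats: multi-model minimal PDB (CA-style beads) and whitespace XYZ
for conformations; 3-column ``.dat`` for scattering curves (see
:mod:`ntdsplay.curves`); small CSV dialects for umbrella windows,
current traces, recovery series, and bias traces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .beads import BeadConformation, ConformationalEnsemble
from .ephys import CurrentTrace, RecoverySeries
from .reweight import BiasTrace
from .wham import UmbrellaWindow

__all__ = [
    "write_ensemble_pdb",
    "read_ensemble_pdb",
    "write_ensemble_xyz",
    "read_ensemble_xyz",
    "write_window_csv",
    "read_window_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_recovery_csv",
    "read_recovery_csv",
    "write_bias_csv",
    "read_bias_csv",
    "write_weights_csv",
    "read_weights_csv",
    "write_frame_matrix",
    "read_frame_matrix",
]


# -- conformations ----------------------------------------------------------


def _to_atom_array(conf: BeadConformation) -> struc.AtomArray:
    n = conf.n_beads
    arr = struc.AtomArray(n)
    arr.coord = conf.coordinates.astype(np.float32)
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.res_name = np.full(n, "BEA")
    arr.res_id = np.arange(1, n + 1)
    if conf.cluster_labels is not None:
        labels = [str(l) for l in conf.cluster_labels]
        uniq = {l: chr(ord("A") + i % 26) for i, l in enumerate(dict.fromkeys(labels))}
        arr.chain_id = np.array([uniq[l] for l in labels])
    else:
        arr.chain_id = np.full(n, "A")
    return arr


def write_ensemble_pdb(path, ensemble: ConformationalEnsemble) -> None:
    """Write frames as MODEL/ENDMDL records of CA-style beads.

    All frames must hold the same number of beads (use XYZ otherwise).
    Cluster labels are mapped to chain IDs; scattering lengths are not
    stored (beads re-read from PDB get unit scattering lengths).
    """
    counts = {f.n_beads for f in ensemble.frames}
    if len(counts) != 1:
        raise ValueError("PDB output requires equal bead counts across frames")
    stack = struc.stack([_to_atom_array(f) for f in ensemble.frames])
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_ensemble_pdb(path) -> ConformationalEnsemble:
    pdb = pdbio.PDBFile.read(path)
    stack = pdb.get_structure()
    frames = [
        BeadConformation(
            stack.coord[m].astype(float),
            cluster_labels=np.asarray(stack.chain_id, dtype=object),
        )
        for m in range(stack.stack_depth())
    ]
    return ConformationalEnsemble(frames)


def write_ensemble_xyz(path, ensemble: ConformationalEnsemble) -> None:
    """Whitespace XYZ: per frame, a bead count line, a comment, then rows."""
    with open(path, "w") as fh:
        for k, f in enumerate(ensemble.frames):
            fh.write(f"{f.n_beads}\nframe {k}\n")
            for (x, y, z), b in zip(f.coordinates, f.scattering_lengths):
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f} {b:.6f}\n")


def read_ensemble_xyz(path) -> ConformationalEnsemble:
    frames = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        rows = [lines[i + 2 + j].split() for j in range(n)]
        coords = np.array([[float(v) for v in r[1:4]] for r in rows])
        b = np.array([float(r[4]) if len(r) > 4 else 1.0 for r in rows])
        frames.append(BeadConformation(coords, scattering_lengths=b))
        i += 2 + n
    return ConformationalEnsemble(frames)


# -- umbrella windows -------------------------------------------------------


def write_window_csv(path, window: UmbrellaWindow) -> None:
    """Header ``center_nm,k_kJ_mol_nm2`` and its values, then one sample/line."""
    with open(path, "w") as fh:
        fh.write("center_nm,k_kJ_mol_nm2\n")
        fh.write(f"{window.center},{window.force_constant}\n")
        for s in window.samples:
            fh.write(f"{s}\n")


def read_window_csv(path) -> UmbrellaWindow:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("center_nm"):
            raise ValueError(f"{path}: expected a center_nm,k_kJ_mol_nm2 header")
        center, k = (float(v) for v in fh.readline().split(","))
        samples = np.array([float(l) for l in fh if l.strip()])
    return UmbrellaWindow(center, k, samples)


# -- electrophysiology ------------------------------------------------------


def write_trace_csv(path, trace: CurrentTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# onset_ms={trace.stimulus_onset}\n")
        fh.write("t_ms,i_pA\n")
        for t, i in zip(trace.t, trace.i):
            fh.write(f"{t},{i}\n")


def read_trace_csv(path) -> CurrentTrace:
    onset = 0.0
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for l in lines:
        if l.startswith("#"):
            if "onset_ms=" in l:
                onset = float(l.split("onset_ms=")[1])
        else:
            body.append(l)
    df = pd.read_csv(pd.io.common.StringIO("".join(body)))
    return CurrentTrace(df["t_ms"].to_numpy(), df["i_pA"].to_numpy(), onset)


def write_recovery_csv(path, series: RecoverySeries) -> None:
    pd.DataFrame(
        {"interval_ms": series.interpulse_intervals, "ratio": series.peak_ratios}
    ).to_csv(path, index=False)


def read_recovery_csv(path) -> RecoverySeries:
    df = pd.read_csv(path)
    return RecoverySeries(df["interval_ms"].to_numpy(), df["ratio"].to_numpy())


# -- reweighting ------------------------------------------------------------


def write_bias_csv(path, trace: BiasTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kT_kJ_mol={trace.kT}\n")
        fh.write("cv_nm,bias_kJ_mol\n")
        for c, v in zip(trace.cv, trace.bias_energy):
            fh.write(f"{c},{v}\n")


def read_bias_csv(path) -> BiasTrace:
    kT = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for l in lines:
        if l.startswith("#"):
            if "kT_kJ_mol=" in l:
                kT = float(l.split("kT_kJ_mol=")[1])
        else:
            body.append(l)
    df = pd.read_csv(pd.io.common.StringIO("".join(body)))
    if kT is None:
        raise ValueError(f"{path}: missing '# kT_kJ_mol=' header")
    return BiasTrace(df["cv_nm"].to_numpy(), df["bias_kJ_mol"].to_numpy(), kT)


def write_weights_csv(path, weights, w0=None) -> None:
    data = {"weight": np.asarray(weights, dtype=float)}
    if w0 is not None:
        data["prior_weight"] = np.asarray(w0, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_weights_csv(path) -> np.ndarray:
    return pd.read_csv(path)["weight"].to_numpy()


def write_frame_matrix(path, q, frame_curves) -> None:
    """Matrix file: first column q, then one intensity column per frame."""
    mat = np.column_stack([np.asarray(q, float)] + [f.I for f in frame_curves])
    np.savetxt(path, mat, header="q[1/A] I_frame_0 ...")


def read_frame_matrix(path):
    """Returns ``(q, I)`` with I of shape (n_frames, n_q)."""
    mat = np.loadtxt(path, comments="#", ndmin=2)
    return mat[:, 0], mat[:, 1:].T
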
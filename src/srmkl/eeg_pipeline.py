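"""Optional front-end for the Bonn University epilepsy EEG sets A-E.

The Bonn corpus distributes five sets of 100 single-channel recordings as
plain ASCII, one integer amplitude per line.  Sets A and B are surface
recordings of healthy volunteers; C, D and E are intracranial recordings of
epilepsy patients (E during seizures).  Each set is treated as one style
group; the binary task is healthy (+1) vs patient (-1).

Recordings are reduced to a fixed-length feature vector by kernel PCA
(default 70 components, gaussian kernel at the median-distance heuristic
width — the corpus-standard dimensionality; the original kernel settings of
published experiments are typically unstated, so this is a documented
convention, not a reproduction guarantee).

Nothing here is required by the rest of the package: the classifiers consume
any StyleGroupedDataset, and the test suite uses tiny synthetic recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import KernelPCA

from .errors import InputError
from .kernel_bank import BaseKernelSpec, compute_gram
from .style_transform import StyleGroupedDataset
from .synthetic_data import SplitPlan, make_splits

#: Bonn set letter -> historical file-name code letter
SET_CODES = {"A": "Z", "B": "O", "C": "N", "D": "F", "E": "S"}
#: Bonn set -> class label (healthy +1, patient -1)
SET_LABELS = {"A": 1.0, "B": 1.0, "C": -1.0, "D": -1.0, "E": -1.0}
#: Bonn set -> style-group id
SET_GROUPS = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}


@dataclass
class BonnRecording:
    """One ASCII recording: its set, integer amplitudes, and source file name."""

    set_id: str
    values: np.ndarray
    source_file: str

    def __post_init__(self) -> None:
        if self.set_id not in SET_CODES:
            raise InputError(f"unknown Bonn set {self.set_id!r}; expected A-E")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise InputError(f"{self.source_file}: empty recording")


def _parse_ascii(path: Path) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue  # tolerate blank (e.g. trailing) lines
            try:
                vals.append(int(s))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: not an integer amplitude: {s!r}") from exc
    return np.array(vals, dtype=float)


def load_bonn(dir_path: str | Path,
              sets: Sequence[str] = ("A", "B", "C", "D", "E")) -> list[BonnRecording]:
    """Load Bonn ASCII recordings from ``dir_path``.

    Each requested set must live in a subdirectory named either by its set
    letter (``A`` .. ``E``) or by its historical code letter (``Z``, ``O``,
    ``N``, ``F``, ``S``); every ``*.txt``/``*.TXT`` file inside is one
    recording with one integer per line.
    """
    root = Path(dir_path)
    out: list[BonnRecording] = []
    for set_id in sets:
        if set_id not in SET_CODES:
            raise InputError(f"unknown Bonn set {set_id!r}")
        candidates = [root / set_id, root / SET_CODES[set_id],
                      root / set_id.lower(), root / SET_CODES[set_id].lower()]
        sub = next((c for c in candidates if c.is_dir()), None)
        if sub is None:
            raise InputError(
                f"set {set_id} not found under {root}; expected a subdirectory named "
                f"{set_id!r} or {SET_CODES[set_id]!r} containing one-integer-per-line "
                "ASCII files (*.txt)")
        files = sorted(p for p in sub.iterdir()
                       if p.is_file() and p.suffix.lower() == ".txt")
        if not files:
            raise InputError(f"set {set_id}: no *.txt recordings in {sub}")
        for p in files:
            out.append(BonnRecording(set_id, _parse_ascii(p), p.name))
    return out


def kpca_features(recordings: Sequence[BonnRecording], n_components: int = 70,
                  kernel: BaseKernelSpec | None = None) -> StyleGroupedDataset:
    """Reduce whole recordings to KPCA feature rows; one row per recording.

    Recordings are truncated to the shortest common length.  The centered
    kernel PCA projection has (numerically) zero mean in feature space.
    """
    if not recordings:
        raise InputError("no recordings supplied")
    if n_components > len(recordings):
        raise InputError(f"n_components={n_components} exceeds {len(recordings)} recordings")
    L = min(r.values.size for r in recordings)
    R = np.vstack([r.values[:L] for r in recordings])
    if kernel is None:
        med = float(np.median(pdist(R))) or 1.0
        kernel = BaseKernelSpec("gaussian", width=med)
    K = compute_gram(kernel, R)
    X = KernelPCA(n_components=n_components, kernel="precomputed").fit_transform(K)
    y = np.array([SET_LABELS[r.set_id] for r in recordings])
    g = np.array([SET_GROUPS[r.set_id] for r in recordings])
    return StyleGroupedDataset(X, y, g)


#: dataset id -> (sets used, default held-out set or None)
#: The held-out assignment of the two unseen-style designs is configurable;
#: the published experiment table does not identify it.
PAPER_SPLITS = {
    "DS.1": (("A", "B", "E"), None),
    "DS.2": (("B", "D", "E"), None),
    "DS.3": (("A", "C", "E"), "C"),
    "DS.4": (("A", "C", "E"), "A"),
}


def build_paper_splits(dataset: StyleGroupedDataset, ds_id: str, seed: int,
                       held_out: str | None = None
                       ) -> tuple[StyleGroupedDataset, StyleGroupedDataset]:
    """Assemble one of the four benchmark splits over the Bonn sets.

    DS.1/DS.2 are 50/50 within-group splits (every test style trains too);
    DS.3/DS.4 hold one whole set out of training.  ``held_out`` overrides
    the default holdout of the unseen-style designs.
    """
    if ds_id not in PAPER_SPLITS:
        raise InputError(f"unknown dataset id {ds_id!r}; expected one of {sorted(PAPER_SPLITS)}")
    sets, default_held = PAPER_SPLITS[ds_id]
    held = held_out if held_out is not None else default_held
    if held is not None and held not in sets:
        raise InputError(f"held-out set {held!r} is not part of {ds_id} ({sets})")
    keep_ids = {SET_GROUPS[s] for s in sets}
    mask = np.isin(dataset.group, sorted(keep_ids))
    if not mask.any():
        raise InputError(f"dataset contains none of the sets {sets}")
    sub = dataset.subset(np.flatnonzero(mask))
    held_ids = frozenset({SET_GROUPS[held]}) if held is not None else frozenset()
    return make_splits(sub, SplitPlan(0.5, held_ids), seed)
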
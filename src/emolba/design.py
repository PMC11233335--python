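"""The 2x2 design (picture pleasantness x anticipated search difficulty),
normative/aberrant response coding, and the null vs. core parameter maps.

Design cells
------------
Pleasantness comes from the picture's normative valence on the 1-9 scale
(norm < 5 -> the normative report is "unpleasant"); difficulty comes from
the visual-search cue shown before the picture: feature searches (color or
shape) are easy, conjunction search is difficult.

Models
------
``null``  — 5 free subject-level parameters: A, B, t0, mean_v.normative,
            mean_v.aberrant, all shared across the 4 cells.
``core``  — 14 free subject-level parameters: A and t0 shared; B,
            mean_v.normative and mean_v.aberrant each split over the 4
            cells. The core model nests the null model: collapsing the
            splits reproduces null likelihoods exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lba import CellParams

PLEASANTNESS = ("unpleasant", "pleasant")
DIFFICULTY = ("easy", "difficult")

#: canonical cell order used everywhere (arrays, parameter names, reports)
CELLS: tuple[tuple[str, str], ...] = (
    ("unpleasant", "easy"),
    ("unpleasant", "difficult"),
    ("pleasant", "easy"),
    ("pleasant", "difficult"),
)

CELL_INDEX = {cell: i for i, cell in enumerate(CELLS)}

_CUE_MAP = {"color": "easy", "shape": "easy", "conjunction": "difficult"}

#: prior location and SD for each base parameter (estimation defaults)
PRIOR_TABLE = {
    "A": (2.0, 0.6),
    "B": (2.0, 0.6),
    "t0": (0.3, 0.1),
    "mean_v.normative": (2.0, 0.8),
    "mean_v.aberrant": (0.5, 0.8),
}

#: support lower bound per base parameter (np.NINF = unbounded)
LOWER_BOUND = {
    "A": 0.0,
    "B": 0.0,
    "t0": 0.0,
    "mean_v.normative": -np.inf,
    "mean_v.aberrant": -np.inf,
}


class DesignError(ValueError):
    """Unknown design label or malformed model specification."""


class UndefinedNormError(ValueError):
    """A picture norm of exactly 5 has no normative response."""


def cue_to_difficulty(cue: str) -> str:
    """Collapse the search cue to its anticipated difficulty level."""
    try:
        return _CUE_MAP[cue]
    except KeyError:
        raise DesignError(f"unknown search cue {cue!r}; expected one of {sorted(_CUE_MAP)}")


def norm_to_pleasantness(picture_norm: float) -> str:
    """Normative pleasantness of a picture from its 1-9 valence norm."""
    if not 1.0 <= picture_norm <= 9.0:
        raise DesignError(f"picture norm {picture_norm} outside [1, 9]")
    if picture_norm == 5.0:
        raise UndefinedNormError("norm exactly 5 has no normative response")
    return "unpleasant" if picture_norm < 5.0 else "pleasant"


def code_response(picture_norm: float, report: str) -> str:
    """Code a pleasant/unpleasant report as normative or aberrant.

    A report is normative when it matches the side of the neutral point (5)
    on which the picture's valence norm lies.
    """
    if report not in ("pleasant", "unpleasant"):
        raise DesignError(f"unknown report {report!r}")
    return "normative" if norm_to_pleasantness(picture_norm) == report else "aberrant"


def cell_of(picture_norm: float, cue: str) -> tuple[str, str]:
    """Map a trial's picture norm and cue to its design cell."""
    return (norm_to_pleasantness(picture_norm), cue_to_difficulty(cue))


def report_for_choice(picture_norm: float, choice: str) -> str:
    """Stimulus-relative -> response-absolute recoding (utility; unused in fitting)."""
    pleas = norm_to_pleasantness(picture_norm)
    if choice == "normative":
        return pleas
    if choice == "aberrant":
        return "pleasant" if pleas == "unpleasant" else "unpleasant"
    raise DesignError(f"unknown choice {choice!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Mapping from design cells to free subject-level parameters.

    ``param_names`` orders the free-parameter vector theta; split parameters
    carry a cell suffix, e.g. ``B[pleasant,difficult]``.
    """

    name: str
    shared: tuple[str, ...]
    split: tuple[str, ...]

    @property
    def param_names(self) -> tuple[str, ...]:
        names = list(self.shared)
        for base in self.split:
            names += [f"{base}[{p},{d}]" for (p, d) in CELLS]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.shared) + 4 * len(self.split)

    def base_of(self, param: str) -> str:
        return param.split("[")[0]

    def prior_loc_sd(self) -> tuple[np.ndarray, np.ndarray]:
        locs, sds = [], []
        for p in self.param_names:
            loc, sd = PRIOR_TABLE[self.base_of(p)]
            locs.append(loc)
            sds.append(sd)
        return np.array(locs), np.array(sds)

    def lower_bounds(self) -> np.ndarray:
        return np.array([LOWER_BOUND[self.base_of(p)] for p in self.param_names])

    def _index(self, base: str, cell_i: int) -> int:
        if base in self.shared:
            return self.shared.index(base)
        off = len(self.shared) + 4 * self.split.index(base)
        return off + cell_i

    def expand_many(self, thetas: np.ndarray) -> np.ndarray:
        """(m, n_free) theta matrix -> (m, 4, 6) kernel cell-parameter arrays.

        Kernel columns: [A, b, v_normative, v_aberrant, sv, t0]; b = A + B.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        m = thetas.shape[0]
        if thetas.shape[1] != self.n_free:
            raise DesignError(
                f"theta length {thetas.shape[1]} != {self.n_free} for model {self.name!r}"
            )
        out = np.empty((m, 4, 6))
        for k in range(4):
            A = thetas[:, self._index("A", k)]
            out[:, k, 0] = A
            out[:, k, 1] = A + thetas[:, self._index("B", k)]
            out[:, k, 2] = thetas[:, self._index("mean_v.normative", k)]
            out[:, k, 3] = thetas[:, self._index("mean_v.aberrant", k)]
            out[:, k, 4] = 1.0  # sv fixed (scaling constraint)
            out[:, k, 5] = thetas[:, self._index("t0", k)]
        return out

    def expand_subject_params(self, theta: np.ndarray) -> dict[tuple[str, str], CellParams]:
        """theta -> fully populated CellParams per design cell."""
        arr = self.expand_many(np.asarray(theta))[0]
        out = {}
        for cell, row in zip(CELLS, arr):
            A, b, vn, va, sv, t0 = row
            out[cell] = CellParams.make(
                A=A, B=b - A, mean_v_normative=vn, mean_v_aberrant=va, sv=sv, t0=t0
            )
        return out

    def flatten(self, cell_params: dict[tuple[str, str], CellParams]) -> np.ndarray:
        """Inverse of expand_subject_params (exact round trip)."""
        theta = np.empty(self.n_free)
        for k, cell in enumerate(CELLS):
            cp = cell_params[cell]
            theta[self._index("A", k)] = cp.normative.A
            theta[self._index("B", k)] = cp.normative.B
            theta[self._index("mean_v.normative", k)] = cp.normative.mean_v
            theta[self._index("mean_v.aberrant", k)] = cp.aberrant.mean_v
            theta[self._index("t0", k)] = cp.normative.t0
        return theta

    def to_dict(self) -> dict:
        return {"model": self.name, "shared": list(self.shared), "split": list(self.split)}


NULL_MODEL = ModelSpec(
    name="null",
    shared=("A", "B", "t0", "mean_v.normative", "mean_v.aberrant"),
    split=(),
)

CORE_MODEL = ModelSpec(
    name="core",
    shared=("A", "t0"),
    split=("B", "mean_v.normative", "mean_v.aberrant"),
)

MODELS = {"null": NULL_MODEL, "core": CORE_MODEL}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise DesignError(f"unknown model {name!r}; expected 'null' or 'core'")
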
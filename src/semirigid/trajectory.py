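"""Coordinate trajectories: an ordered stack of frames over a fixed atom set.

Coordinates are stored in nanometres throughout the package; readers convert
on input (PDB files are in Angstrom and are scaled by 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SelectionError, SemirigidError

#: Columns every ``atom_meta`` table carries, in order.
ATOM_META_COLUMNS = ("atom_name", "res_id", "res_name", "chain_id")


def default_atom_meta(n_atoms: int) -> pd.DataFrame:
    """Placeholder per-atom metadata for trajectories built from bare arrays."""
    return pd.DataFrame(
        {
            "atom_name": ["CA"] * n_atoms,
            "res_id": np.arange(1, n_atoms + 1),
            "res_name": ["ALA"] * n_atoms,
            "chain_id": ["A"] * n_atoms,
        }
    )


@dataclass
class Trajectory:
    """Frames of 3D coordinates for a fixed, ordered atom set.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.  Every frame must
        contain the same atoms in the same order.
    atom_meta
        Per-atom table with columns ``atom_name``, ``res_id``, ``res_name``,
        ``chain_id``.  Built automatically if omitted.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SemirigidError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.n_frames < 1:
            raise SemirigidError("a trajectory needs at least one frame")
        bad = ~np.isfinite(self.coords)
        if bad.any():
            frame, atom, _ = np.argwhere(bad)[0]
            raise SemirigidError(
                f"non-finite coordinate at frame {frame}, atom {atom}"
            )
        if self.atom_meta is None:
            self.atom_meta = default_atom_meta(self.n_atoms)
        else:
            self.atom_meta = self.atom_meta.reset_index(drop=True)
            missing = set(ATOM_META_COLUMNS) - set(self.atom_meta.columns)
            if missing:
                raise SemirigidError(f"atom_meta lacks columns {sorted(missing)}")
            if len(self.atom_meta) != self.n_atoms:
                raise SemirigidError(
                    f"atom_meta has {len(self.atom_meta)} rows for "
                    f"{self.n_atoms} atoms"
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    # -- subsetting ---------------------------------------------------------

    def select(self, atom_names) -> "Trajectory":
        """Restrict to atoms whose name is in ``atom_names``.

        ``atom_names`` may be a single name (e.g. ``"CA"``, the conventional
        backbone alpha-carbon selection) or an iterable of names.  ``None``
        returns the trajectory unchanged.
        """
        if atom_names is None:
            return self
        if isinstance(atom_names, str):
            atom_names = (atom_names,)
        mask = self.atom_meta["atom_name"].isin(list(atom_names)).to_numpy()
        if not mask.any():
            raise SelectionError(
                f"selection {tuple(atom_names)!r} matches no atoms"
            )
        return Trajectory(self.coords[:, mask], self.atom_meta.loc[mask])

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over the half-open frame range ``[start, stop)``."""
        if not (0 <= start < stop <= self.n_frames):
            raise SemirigidError(
                f"frame range [{start}, {stop}) outside 0..{self.n_frames}"
            )
        return Trajectory(self.coords[start:stop], self.atom_meta)

    def second_half(self) -> "Trajectory":
        """Drop the first half of the frames.

        MD trajectories typically need an equilibration period before they
        sample phase space without memory of the start configuration; the
        customary remedy is to analyse only the second half of the run.
        """
        return self.slice_frames(self.n_frames // 2, self.n_frames)
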
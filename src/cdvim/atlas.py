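"""Atlas-based stereotactic Vim targeting from AC-PC landmarks.

The surgical standard places the Vim target relative to the mid-commissural
point: AP = (AC-PC length)/3 - 2 mm anterior to the PC, ML = midline
+/- 12-14 mm (12.5 mm default), SI = 0 relative to the axial AC-PC plane.

For landmarks that are not axis-aligned the target is constructed in an
AC-PC local frame: y along PC->AC, x the world-ML direction orthogonalised
against it, z completing the right-handed frame (so the midsagittal plane is
spanned by y and z).  This reduces to the world frame when AC and PC sit on
the y axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import Landmarks

DEFAULT_ML_OFFSET_MM = 12.5


@dataclass(frozen=True)
class AtlasTarget:
    left: np.ndarray  # world mm
    right: np.ndarray
    mcp: np.ndarray
    acpc_length_mm: float
    warning: str | None = None


def mid_commissural_point(landmarks: Landmarks) -> np.ndarray:
    """Midpoint of the AC-PC line."""
    return (landmarks.ac + landmarks.pc) / 2.0


def _acpc_frame(landmarks: Landmarks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u_y = landmarks.ac - landmarks.pc
    u_y = u_y / np.linalg.norm(u_y)
    e_x = np.array([1.0, 0.0, 0.0])
    u_x = e_x - (e_x @ u_y) * u_y
    nrm = np.linalg.norm(u_x)
    if nrm < 1e-9:
        raise ValueError("AC-PC line is parallel to the ML axis; frame undefined")
    u_x /= nrm
    u_z = np.cross(u_x, u_y)
    return u_x, u_y, u_z


def atlas_vim_coordinates(
    landmarks: Landmarks, ml_offset: float = DEFAULT_ML_OFFSET_MM
) -> AtlasTarget:
    """Both hemispheres' atlas targets from the commissural landmarks.

    ``ml_offset`` outside the conventional 12-14 mm band is allowed but the
    default follows the 12.5 mm convention.  A warning status is set when the
    AC-PC length is so short (<= 6 mm) that the AP rule would place the
    target behind the PC.
    """
    length = float(np.linalg.norm(landmarks.ac - landmarks.pc))
    u_x, u_y, _ = _acpc_frame(landmarks)
    ap_from_pc = length / 3.0 - 2.0
    warning = None
    if length <= 6.0:
        warning = "AC-PC length <= 6 mm: atlas AP rule places the target at or behind the PC"
    base = landmarks.pc + ap_from_pc * u_y
    return AtlasTarget(
        left=base - ml_offset * u_x,
        right=base + ml_offset * u_x,
        mcp=mid_commissural_point(landmarks),
        acpc_length_mm=length,
        warning=warning,
    )
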
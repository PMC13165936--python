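import numpy as np
import pytest

from pupilkit.geometry import EllipseGeometry


def ellipse_points(ellipse: EllipseGeometry, angles) -> np.ndarray:
    """Exact boundary points of an ellipse at the given parameter angles."""
    angles = np.asarray(angles, float)
    ca, sa = np.cos(ellipse.phi), np.sin(ellipse.phi)
    ex = ellipse.a_semi * np.cos(angles)
    ey = ellipse.b_semi * np.sin(angles)
    return np.column_stack(
        [ellipse.xc + ca * ex - sa * ey, ellipse.yc + sa * ex + ca * ey]
    )


@pytest.fixture
def octagon_angles():
    """The eight 45°-spaced parameter angles of the boundary keypoints."""
    return np.deg2rad(np.arange(8) * 45.0)


@pytest.fixture
def reference_ellipse():
    """A generic tilted ellipse used across the geometry tests."""
    return EllipseGeometry(xc=5.0, yc=4.0, a_semi=3.0, b_semi=2.0, phi=np.pi / 6)


def write_dlc_text(path, bodyparts, frames, scorer="net"):
    """Write a keypoint CSV by hand (independent of the package writer).

    ``frames`` maps frame index -> {bodypart: (x, y, likelihood)}; None
    entries become empty cells.
    """
    cols = [f"{scorer}" for _ in bodyparts for _ in range(3)]
    bps = [bp for bp in bodyparts for _ in range(3)]
    coords = [c for _ in bodyparts for c in ("x", "y", "likelihood")]
    lines = [
        "scorer," + ",".join(cols),
        "bodyparts," + ",".join(bps),
        "coords," + ",".join(coords),
    ]
    for idx in sorted(frames):
        row = [str(idx)]
        for bp in bodyparts:
            rec = frames[idx].get(bp)
            if rec is None:
                row += ["", "", ""]
            else:
                row += [repr(v) if v is not None else "" for v in rec]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path
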
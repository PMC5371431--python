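import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from embryomech.opening_quantification import CutROI, OpeningSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_series(
    times_s: np.ndarray,
    b_um: np.ndarray,
    l_um: float = 5.0,
    pixel_size_um: float = 0.1,
    a_um: np.ndarray | None = None,
) -> OpeningSeries:
    """Opening series built directly from minor-axis values (no imaging)."""
    b_px = np.asarray(b_um, dtype=float) / pixel_size_um
    a_px = (
        np.full_like(b_px, l_um / pixel_size_um)
        if a_um is None
        else np.asarray(a_um, dtype=float) / pixel_size_um
    )
    frame = pd.DataFrame(
        dict(
            time_s=np.asarray(times_s, dtype=float),
            a_px=np.maximum(a_px, b_px),
            b_px=b_px,
            angle_vs_cut_deg=0.0,
            measured=True,
        )
    )
    cut = CutROI(x_px=0.0, y_px=0.0, direction="AP", length_um=l_um)
    return OpeningSeries(frame=frame, cut=cut, pixel_size_um=pixel_size_um)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
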
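import numpy as np
import pytest

from irfg.preprocess import Spectrum, default_grid
from irfg.spectra_io import RawSpectrum, write_jcampdx


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture()
def jcamp_file(tmp_path):
    """Factory writing a minimal AFFN JCAMP-DX file and returning its path."""

    def make(
        wavenumbers,
        intensities,
        yunits="ABSORBANCE",
        name="spec.jdx",
        xunits="1/CM",
        descending=False,
    ):
        x = np.asarray(wavenumbers, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if descending:
            x, y = x[::-1], y[::-1]
        lines = [
            "##TITLE=test",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=INFRARED SPECTRUM",
            f"##XUNITS={xunits}",
            f"##YUNITS={yunits}",
            "##XFACTOR=1.0",
            "##YFACTOR=1.0",
            f"##FIRSTX={x[0]}",
            f"##LASTX={x[-1]}",
            f"##NPOINTS={x.size}",
            "##XYDATA=(X++(Y..Y))",
        ]
        for i in range(0, x.size, 6):
            chunk = y[i : i + 6]
            lines.append(f"{x[i]:.4f} " + " ".join(f"{v:.8g}" for v in chunk))
        lines.append("##END=")
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return make


@pytest.fixture()
def tiny_grid():
    """A 13-point grid (1000..1120 by 10) for fast network/attribution tests."""
    return np.linspace(1000.0, 1120.0, 13)


@pytest.fixture()
def flat_spectrum(grid):
    return Spectrum(grid, np.zeros(grid.size))
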
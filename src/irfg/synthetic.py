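"""Synthetic labeled IR spectra for pipeline development and validation.

Each present functional group contributes Gaussian absorption bands drawn
from a per-group band table (center sampled uniformly within the band's
characteristic wavenumber range, width and relative intensity fixed per
band). On top of the group bands the generator adds fingerprint-region
clutter (small random peaks below 1800 cm^-1), a smooth sinusoidal baseline
drift and white noise, then min-max normalizes to [0, 1].

Band provenance: the entries for methyl, aromatics, alkyl halides (C-F) and
ether follow standard characteristic-absorption ranges for those groups
(C-H stretch 2970-2860, aromatic C-H 3130-3070, C-F 1400-1000, C-O
1300-1000 cm^-1 etc.). All remaining entries are fixture constants taken
from common IR correlation-table values; they make the classes mutually
distinguishable but are not calibrated against measured intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import GROUP_NAMES, N_GROUPS
from .preprocess import DatasetRecord, Spectrum, default_grid, normalize_minmax
from .spectra_io import RawSpectrum, write_jcampdx

__all__ = [
    "Band",
    "BAND_CATALOG",
    "SimConfig",
    "generate_spectrum",
    "generate_dataset",
    "write_dataset_jcampdx",
    "fixture_molecules",
]


@dataclass(frozen=True)
class Band:
    """One characteristic absorption band: center range, width, strength."""

    lo: float  # cm^-1
    hi: float  # cm^-1
    width: float  # Gaussian sd, cm^-1
    intensity: float  # relative peak height in [0, 1]


#: Characteristic bands per functional group, keyed by catalog name.
BAND_CATALOG: dict[str, tuple[Band, ...]] = {
    # C-H stretch, CH2 scissor, long-chain rock
    "alkane": (Band(2850, 2960, 25, 0.7), Band(1440, 1480, 15, 0.35), Band(720, 730, 8, 0.3)),
    # C-H stretch 2970-2860, C-H bend 1470-1370
    "methyl": (Band(2860, 2970, 25, 0.7), Band(1370, 1470, 15, 0.4)),
    # =C-H stretch, C=C stretch, out-of-plane bend
    "alkene": (Band(3010, 3100, 20, 0.4), Band(1620, 1680, 12, 0.5), Band(900, 1000, 20, 0.5)),
    # terminal C-H stretch, C#C stretch
    "alkyne": (Band(3270, 3330, 15, 0.6), Band(2100, 2150, 10, 0.35)),
    # broad O-H stretch, C-O stretch
    "alcohols": (Band(3200, 3550, 80, 0.8), Band(1050, 1150, 20, 0.5)),
    # N-H stretch (narrower than O-H), N-H bend, C-N stretch
    "amines": (Band(3300, 3500, 25, 0.5), Band(1580, 1650, 15, 0.4), Band(1020, 1250, 20, 0.3)),
    # C#N stretch
    "nitriles": (Band(2210, 2260, 10, 0.6),),
    # aromatic C-H 3130-3070, ring C=C pair, out-of-plane C-H 900-670
    "aromatics": (
        Band(3070, 3130, 20, 0.3),
        Band(1580, 1615, 10, 0.4),
        Band(1450, 1510, 10, 0.45),
        Band(670, 900, 20, 0.6),
    ),
    # C-F stretch 1400-1000; heavier-halide C-X stretch at the low end
    "alkyl halides": (Band(1000, 1400, 15, 0.6), Band(600, 800, 15, 0.8)),
    # ester C=O, C-O-C asymmetric stretch
    "esters": (Band(1735, 1750, 12, 0.9), Band(1150, 1300, 18, 0.6)),
    # ketone C=O, C-C-C bend
    "ketones": (Band(1705, 1725, 12, 0.9), Band(1100, 1230, 18, 0.3)),
    # aldehydic C-H (Fermi doublet region), C=O
    "aldehydes": (Band(2695, 2830, 18, 0.4), Band(1720, 1740, 12, 0.9)),
    # very broad O-H, C=O, C-O
    "carboxylic acids": (
        Band(2500, 3300, 150, 0.6),
        Band(1700, 1725, 12, 0.9),
        Band(1210, 1320, 18, 0.4),
    ),
    # C-O-C stretch 1300-1000
    "ether": (Band(1000, 1300, 18, 0.7),),
    # acid-halide C=O (highest carbonyl)
    "acyl halides": (Band(1785, 1815, 10, 0.9),),
    # N-H stretch, amide I (C=O), amide II (N-H bend)
    "amides": (Band(3350, 3500, 30, 0.5), Band(1630, 1700, 14, 0.9), Band(1550, 1640, 14, 0.5)),
    # asymmetric and symmetric NO2 stretches
    "nitro": (Band(1500, 1550, 12, 0.8), Band(1290, 1372, 12, 0.6)),
}

assert set(BAND_CATALOG) == set(GROUP_NAMES)


@dataclass
class SimConfig:
    """Knobs of the synthetic-spectrum generator.

    ``label_count_probs[i]`` is the probability of a sample carrying ``i+1``
    functional groups (default uniform on 1..5, matching the 1-5 groups per
    molecule that dominate curated IR datasets). Noise and drift amplitudes
    are on the pre-normalization absorbance scale.
    """

    n_samples: int = 1000
    label_count_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    noise_sd: float = 0.02
    drift_amplitude: float = 0.05
    clutter_amplitude: float = 0.1
    clutter_max_peaks: int = 8
    intensity_jitter: float = 0.3
    seed: int = 0
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self):
        p = np.asarray(self.label_count_probs, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("label_count_probs must be a probability vector")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _gaussian(grid: np.ndarray, center: float, sd: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((grid - center) / sd) ** 2)


def generate_spectrum(
    labels: np.ndarray,
    config: SimConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Render one spectrum for a 17-bit label vector.

    Deterministic given the seed. With all-zero labels and zero noise, drift
    and clutter, the output is a flat zero spectrum.
    """
    config = config or SimConfig()
    labels = np.asarray(labels)
    if labels.shape != (N_GROUPS,):
        raise ValueError(f"labels must have length {N_GROUPS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    grid = config.grid
    y = np.zeros_like(grid)
    for gi in np.flatnonzero(labels):
        for band in BAND_CATALOG[GROUP_NAMES[gi]]:
            center = rng.uniform(band.lo, band.hi)
            jitter = rng.uniform(1 - config.intensity_jitter, 1 + config.intensity_jitter)
            y += _gaussian(grid, center, band.width, band.intensity * jitter)
    if config.clutter_amplitude > 0 and config.clutter_max_peaks > 0:
        for _ in range(int(rng.integers(0, config.clutter_max_peaks + 1))):
            center = rng.uniform(grid[0], 1800.0)
            y += _gaussian(
                grid,
                center,
                rng.uniform(5, 20),
                rng.uniform(0.2, 1.0) * config.clutter_amplitude,
            )
    if config.drift_amplitude > 0:
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        y += config.drift_amplitude * (
            0.5 + 0.5 * np.sin(2 * np.pi * (rng.uniform(0.25, 1.0) * t + rng.uniform(0, 1)))
        )
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=grid.size)
    y = np.clip(normalize_minmax(np.clip(y, 0.0, None)), 0.0, 1.0)
    return Spectrum(grid, y)


def _draw_labels(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    k = int(rng.choice(len(config.label_count_probs), p=config.label_count_probs)) + 1
    groups = rng.choice(N_GROUPS, size=k, replace=False)
    labels = np.zeros(N_GROUPS, dtype=np.int8)
    labels[groups] = 1
    return labels


def generate_dataset(config: SimConfig | None = None) -> list[DatasetRecord]:
    """Draw ``n_samples`` labeled records; ids are ``synth-00000``-style and
    SMILES is ``None`` (the spectra are not tied to real molecules)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_samples):
        labels = _draw_labels(rng, config)
        spectrum = generate_spectrum(labels, config, rng)
        records.append(
            DatasetRecord(
                id=f"synth-{i:05d}",
                smiles=None,
                spectrum=spectrum,
                labels=labels,
                timestamp="2024-01-01T00:00:00+00:00",
            )
        )
    return records


def write_dataset_jcampdx(records: list[DatasetRecord], out_dir: str | Path) -> Path:
    """Write one .jdx per record plus a TSV manifest; returns the manifest path.

    Records without SMILES get a benzene placeholder so the manifest stays
    consumable by the preprocessing pipeline (the placeholder is marked in
    the id, not silently hidden).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["id\tsmiles\tjcamp_path\ttimestamp"]
    for rec in records:
        fname = f"{rec.id}.jdx"
        raw = RawSpectrum(
            rec.spectrum.grid, rec.spectrum.intensities, "absorbance", {"title": rec.id}
        )
        write_jcampdx(out_dir / fname, raw, title=rec.id)
        rows.append(f"{rec.id}\t{rec.smiles or ''}\t{fname}\t{rec.timestamp}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# fixture molecules

#: (SMILES, frozen expected positive groups). The expected labels were
#: cross-checked against an independent reading of each structure; they are
#: asserted equal to the catalog's output in the test suite.
FIXTURE_MOLECULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("COc1ccc(F)cc1", ("methyl", "aromatics", "alkyl halides", "ether")),  # 4-fluoroanisole
    ("CC(=O)OC", ("alkane", "methyl", "esters")),  # methyl acetate
    ("CC#N", ("alkane", "methyl", "nitriles")),  # acetonitrile
    ("CC(=O)Cl", ("alkane", "methyl", "alkyl halides", "acyl halides")),  # acetyl chloride
    ("NC(=O)c1ccccc1", ("aromatics", "amides")),  # benzamide
    ("C[N+](=O)[O-]", ("methyl", "nitro")),  # nitromethane
    ("CCO", ("alkane", "methyl", "alcohols")),  # ethanol
    ("CC(C)O", ("alkane", "methyl", "alcohols")),  # isopropanol
    ("CCOC(=O)c1ccccc1", ("alkane", "methyl", "aromatics", "esters")),  # ethyl benzoate
    ("COC(=O)c1ccc(OC)cc1", ("methyl", "aromatics", "esters", "ether")),  # methyl 4-methoxybenzoate
    ("c1ccccc1", ("aromatics",)),  # benzene
    ("Cc1ccccc1", ("alkane", "methyl", "aromatics")),  # toluene (sp3 C-H counts as alkane)
    ("CCCCCC", ("alkane", "methyl")),  # hexane
    ("C1CCCCC1", ("alkane",)),  # cyclohexane
    ("CCCCC=C", ("alkane", "methyl", "alkene")),  # 1-hexene
    ("C=Cc1ccccc1", ("alkene", "aromatics")),  # styrene
    ("CC#C", ("alkane", "methyl", "alkyne")),  # propyne
    ("C#Cc1ccccc1", ("alkyne", "aromatics")),  # phenylacetylene
    ("CCN(CC)CC", ("alkane", "methyl", "amines")),  # triethylamine
    ("Nc1ccccc1", ("amines", "aromatics")),  # aniline
    ("CCN", ("alkane", "methyl", "amines")),  # ethylamine
    ("N#Cc1ccccc1", ("nitriles", "aromatics")),  # benzonitrile
    ("CCCl", ("alkane", "methyl", "alkyl halides")),  # chloroethane
    ("BrCCBr", ("alkyl halides",)),  # 1,2-dibromoethane
    ("CC(C)=O", ("alkane", "methyl", "ketones")),  # acetone
    ("CC(=O)c1ccccc1", ("alkane", "methyl", "aromatics", "ketones")),  # acetophenone
    ("O=Cc1ccccc1", ("aromatics", "aldehydes")),  # benzaldehyde
    ("CCC=O", ("alkane", "methyl", "aldehydes")),  # propanal
    ("CC(=O)O", ("alkane", "methyl", "carboxylic acids")),  # acetic acid
    ("OC(=O)c1ccccc1", ("aromatics", "carboxylic acids")),  # benzoic acid
    ("CCOCC", ("alkane", "methyl", "ether")),  # diethyl ether
    ("COc1ccccc1", ("methyl", "aromatics", "ether")),  # anisole
    ("O=C(Cl)c1ccccc1", ("aromatics", "alkyl halides", "acyl halides")),  # benzoyl chloride
    ("CC(N)=O", ("alkane", "methyl", "amides")),  # acetamide
    ("O=[N+]([O-])c1ccccc1", ("aromatics", "nitro")),  # nitrobenzene
    ("Oc1ccccc1", ("alcohols", "aromatics")),  # phenol
    ("C=CC#N", ("alkene", "nitriles")),  # acrylonitrile
    ("FC(F)(F)c1ccccc1", ("aromatics", "alkyl halides")),  # (trifluoromethyl)benzene
)


def fixture_molecules() -> list[tuple[str, np.ndarray]]:
    """Small-molecule panel with frozen expected label vectors.

    Every catalog group is positive in at least two entries, so the panel
    exercises the whole label space.
    """
    from .catalog import DEFAULT_CATALOG

    out = []
    for smiles, names in FIXTURE_MOLECULES:
        bits = np.zeros(N_GROUPS, dtype=np.int8)
        for name in names:
            bits[DEFAULT_CATALOG.index(name)] = 1
        out.append((smiles, bits))
    return out
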
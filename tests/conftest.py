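import numpy as np
import pytest

from ms2derep.spectra_io import LibraryEntry, MassSpectrum


def make_spectrum(
    peaks,
    precursor_mz=300.0,
    spectrum_id="spec",
    charge=1,
    rt=100.0,
    polarity="unknown",
):
    mz, intensities = zip(*peaks)
    return MassSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        mz=np.array(mz, dtype=float),
        intensities=np.array(intensities, dtype=float),
        precursor_charge=charge,
        retention_time=rt,
        polarity=polarity,
    )


def make_entry(peaks, precursor_mz, accession, source, name="", smiles=None):
    return LibraryEntry(
        spectrum=make_spectrum(peaks, precursor_mz=precursor_mz, spectrum_id=accession),
        compound_name=name,
        accession=accession,
        library_source=source,
        smiles=smiles,
    )


@pytest.fixture(scope="session")
def small_library(tmp_path_factory):
    """A 10-compound seeded library (MSP + SDF) shared across tests."""
    from ms2derep.synthetic import generate_library

    out = tmp_path_factory.mktemp("library")
    msp, sdf = generate_library(10, seed=7, out_dir=out)
    return {"msp": msp, "sdf": sdf, "dir": out}


@pytest.fixture(scope="session")
def catalog():
    from ms2derep.synthetic import load_catalog

    return dict(load_catalog())
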
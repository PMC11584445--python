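import numpy as np
import pytest

from coxplosive import EventSequence, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def params():
    return ModelParams(alpha=0.5, lam=2.0)


@pytest.fixture
def event_csv(tmp_path):
    """Factory writing an event CSV from rows of (strain, energy, channel)."""

    def _write(rows, name="events.csv", header="strain,energy,channel"):
        path = tmp_path / name
        lines = [header] + [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def sequence():
    """Small clean microfailure sequence on the central channel."""

    def _make(strains, energies=None, channel="central"):
        strains = np.asarray(strains, dtype=float)
        if energies is None:
            energies = np.full(len(strains), 2.0)
        return EventSequence(
            strains=strains,
            energies=np.asarray(energies, dtype=float),
            channels=np.full(len(strains), channel, dtype=object),
            specimen_id="T01",
        )

    return _make
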
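from pathlib import Path

import pytest

from vancomipd import PatientCovariates, PDParameters, PKParameters

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def pk_params() -> PKParameters:
    return PKParameters()


@pytest.fixture(scope="session")
def pd_params() -> PDParameters:
    return PDParameters()


@pytest.fixture
def typical_adult() -> PatientCovariates:
    """Reference adult: 40 y, 70 kg, normal renal labs, male, no comorbidity."""
    return PatientCovariates(age=40, weight=70, creatinine=1.0, bun=15)


def _load_reference(name, cr_levels, bun_levels):
    """Parse a published nomogram TSV into {(level, wt, cr, bun): dose}."""
    out = {}
    for line in (DATA / name).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        level, wt = float(parts[0]), float(parts[1])
        doses = [float(x) for x in parts[2:]]
        k = 0
        for cr in cr_levels:
            for bun in bun_levels:
                out[(level, wt, cr, bun)] = doses[k]
                k += 1
    return out


@pytest.fixture(scope="session")
def reference_nomograms():
    """Published optimal-dose tables keyed by population."""
    return {
        "adult": _load_reference("nomogram_adult.tsv", [0.5, 1.0, 1.5, 2.0, 2.5], [10, 20, 30, 40]),
        "pediatric": _load_reference("nomogram_pediatric.tsv", [0.5, 1.0, 1.5, 2.0], [10, 15, 20, 25]),
        "under4": _load_reference("nomogram_under4.tsv", [0.3, 0.6, 0.9, 1.2], [5, 10, 15, 20]),
    }
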
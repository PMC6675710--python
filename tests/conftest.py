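import pandas as pd
import pytest
from hypothesis import settings

from romma import CaseRecord, load_equation_specs
from romma.reference_data import VALIDATION_BAND_COUNTS

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_record(**overrides) -> CaseRecord:
    """Complete case record with unremarkable defaults, overridable per test."""
    base = dict(
        case_id="C1",
        patient_id="P1",
        nottingham_score=6,
        er_h_score=200,
        pr_h_score=100,
        her2_ihc=1,
        ki67_pct=20.0,
        tumor_size_cm=2.0,
    )
    base.update(overrides)
    return CaseRecord(**base)


@pytest.fixture(scope="session")
def specs():
    return load_equation_specs()


# Representative amMs value for each cumulative-group increment, and the
# ODXRS representative for each band.
_AMMS_REP = {
    "amMs <9": 7.0,
    "amMs <=10": 9.5,
    "amMs <=11": 10.5,
    "amMs <=12": 11.5,
    "amMs <=14": 13.0,
    "amMs <=15": 14.8,
    "amMs <18": 16.5,
    "amMs >30": 35.0,
}
_ODX_REP = {"high": 31, "intermediate": 20, "low": 10}


@pytest.fixture(scope="session")
def validation_cohort() -> pd.DataFrame:
    """Per-case frame whose cumulative band counts reproduce the published
    validation-population agreement table (620-case study arm, Ki-67 available).

    Cumulative published counts are differenced into per-increment counts and
    expanded into synthetic cases at a representative amMs per increment.
    """
    rows = []
    previous = (0, 0, 0)
    case = 0
    for label, n_high, n_int, n_low in VALIDATION_BAND_COUNTS:
        if label == "histologic low risk":
            continue
        if label == "amMs >30":
            increment = (n_high, n_int, n_low)
        else:
            increment = (n_high - previous[0], n_int - previous[1], n_low - previous[2])
            previous = (n_high, n_int, n_low)
        for band, count in zip(("high", "intermediate", "low"), increment):
            for _ in range(count):
                rows.append(
                    {
                        "case_id": f"V{case:04d}",
                        "amms": _AMMS_REP[label],
                        "odx_rs": _ODX_REP[band],
                        # deliberately fails the histologic low-risk criteria
                        "nottingham_score": 7,
                        "er_h_score": 200,
                        "pr_h_score": 100,
                        "ki67_pct": 20.0,
                    }
                )
                case += 1
    return pd.DataFrame(rows)
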
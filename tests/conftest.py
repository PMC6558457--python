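import numpy as np
import pytest

from lungmarkov import AgeCurve, load_parameters


@pytest.fixture(scope="session")
def base_params():
    """The packaged base case."""
    return load_parameters()


def flat_curve(value: float) -> AgeCurve:
    """An age-constant curve usable for zero or certain mortality."""
    return AgeCurve((0.0, 120.0), (value, value), "linear")


@pytest.fixture()
def immortal_params(base_params):
    """No background, procedure or disease mortality and no progression:
    the whole cohort stays alive through the horizon."""
    return base_params.replace(
        bg_mortality=flat_curve(0.0),
        mort_lobectomy=flat_curve(0.0),
        mort_sabr=0.0,
        mort_conv_rt=0.0,
        mort_progression=0.0,
        p_prog_lob=0.0,
        p_prog_sabr=0.0,
        p_prog_post_salv_lr_sabr=0.0,
        p_prog_post_salv_rr_lob=0.0,
        p_prog_post_salv_rr_sabr=0.0,
    )


@pytest.fixture()
def lethal_procedure_params(base_params):
    """Certain perioperative death in both arms."""
    return base_params.replace(
        mort_lobectomy=flat_curve(1.0),
        mort_sabr=1.0,
    )


def symmetric_params(base_params):
    """Both arms with identical effective parameters: same procedure
    mortality, progression risk, failure splits, salvage and post-salvage
    risks, so their life expectancies must agree."""
    return base_params.replace(
        mort_lobectomy=flat_curve(0.02),
        mort_sabr=0.02,
        p_prog_lob=0.05,
        p_prog_sabr=0.05,
        frac_lr_lob=0.0,
        frac_lr_sabr=0.0,
        frac_rr_lob=0.25,
        frac_rr_sabr=0.25,
        p_salv_rr_lob=0.3,
        p_salv_rr_sabr=0.3,
        p_prog_post_salv_rr_lob=0.2,
        p_prog_post_salv_rr_sabr=0.2,
    )
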
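import pytest

from genodiet.pipeline import default_score_table_path
from genodiet.scoring import load_score_table


@pytest.fixture(scope="session")
def default_table():
    """The shipped (synthetic) 10-SNP score table."""
    return load_score_table(default_score_table_path())


@pytest.fixture(scope="session")
def toy_table():
    """Shipped 3-SNP toy table: 1 / 0.5 / 0 fat points per locus, mirrored carb."""
    from importlib import resources

    return load_score_table(str(resources.files("genodiet") / "data" / "score_table_toy3.yaml"))


@pytest.fixture
def toy_cohort():
    """A small eligible cohort (mixed strata) for randomization tests."""
    import numpy as np

    from genodiet.design import Participant, Sex
    from genodiet.scoring import ResponderClass

    rng = np.random.default_rng(7)
    out = []
    for i in range(60):
        sex = Sex.FEMALE if i % 5 else Sex.MALE
        cls = ResponderClass.FAT_RESPONDER if i % 3 else ResponderClass.CARB_RESPONDER
        bmi = float(rng.uniform(27.0, 47.5))
        height = 165.0
        out.append(
            Participant(
                subject_id=f"P{i:03d}",
                sex=sex,
                race="white",
                age=50.0,
                weight=round(bmi * (height / 100) ** 2, 1),
                height=height,
                bmi=round(bmi, 2),
                responder_class=cls,
            )
        )
    return out
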
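import numpy as np
import pandas as pd
import pytest

from ppeboost import slam_io, synthetic_data as sd

SLAM_FIXTURE = """\
# user:XEinXf5+  countries:CO  days:0.003  client:web  session:lesson  format:reverse_translate  time:9
# prompt:Yo soy un nino
aF97qm0101  I           PRON  Case=Nom  nsubj  2  0
aF97qm0102  am          VERB  Number=Sing  ROOT  0  0
aF97qm0103  a           DET   Definite=Ind  det  4  1

# user:XEinXf5+  countries:CO  days:0.005  client:web  session:lesson  format:reverse_tap  time:5
aF97qm0201  the         DET   Definite=Def  det  2  0
aF97qm0202  boy         NOUN  Number=Sing  ROOT  0  1
"""


@pytest.fixture
def slam_file(tmp_path):
    path = tmp_path / "fixture.slam"
    path.write_text(SLAM_FIXTURE)
    return path


def make_log(rows):
    """Build a canonical event log from (user, token, day, label) tuples."""
    df = pd.DataFrame(rows, columns=["user", "token", "day", "label"])
    return slam_io.canonicalize(df)


@pytest.fixture(scope="session")
def sim_log():
    """One default-condition simulated log shared across the suite."""
    log, truth = sd.simulate(seed=202)
    return log, truth


@pytest.fixture(scope="session")
def sim_split(sim_log):
    log, _ = sim_log
    split = slam_io.chronological_split(log, 0.9)
    kept = slam_io.filter_test_first_repetition(split)
    return split, kept


@pytest.fixture
def rng():
    return np.random.default_rng(7)
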
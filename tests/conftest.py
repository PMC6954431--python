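import logging

import pytest

from sugarcdl.dictionary import RestraintDictionary
from sugarcdl.recovery import closed_loop_recovery

logging.getLogger("sugarcdl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def this_work():
    return RestraintDictionary.load("this-work")


@pytest.fixture(scope="session")
def parkinson():
    return RestraintDictionary.load("parkinson")


@pytest.fixture(scope="session")
def closed_loop():
    """One shared run of the generate -> derive -> compare ensemble.

    Expensive (a couple of minutes); every closed-loop assertion reads
    from this single result.
    """
    return closed_loop_recovery(seed=0)
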
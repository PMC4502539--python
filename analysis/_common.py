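"""Shared settings for the numbered analysis drivers.

Every driver regenerates the corpus deterministically from SEED (the
generator is bit-reproducible), so the scripts can run independently or in
order. Outputs land under results/.
"""

from pathlib import Path

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    CORPUS.mkdir(exist_ok=True)
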
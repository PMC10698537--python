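"""Shared paths and study-scale constants for the analysis scripts.

The drivers form a chain (01 -> 06); intermediate binary state (slides,
trained fold models, encoders) lives under scratch/, all tables and reports
under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

MASTER_SEED = 42

# imaging arm: desk-scale slide cohort
N_SLIDES = 24
SLIDE_PX = 128
PATCH_PX = 32

# survival arm
N_PATIENTS = 120
N_BOOT = 200


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def need(path: Path, producer: str):
    if not path.exists():
        raise SystemExit(f"missing {path}; run analysis/{producer} first")
    return path
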
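"""End-to-end session analysis: parse, join, measure, summarize.

Thin orchestration over the parser, metrics and analytics modules so
the CLI, the reporting layer and scripted analyses share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from .analytics import SessionSummary, summarize_session
from .dialect import AddressMap, SYNTHETIC_ADDRESS_MAP
from .epu import ParsedSession, parse_session
from .metrics import MetricParameters, MicrographQuality, compute_all_qualities
from .preproc import (JoinedMicrograph, JoinResult, PreprocResults,
                      join_to_session, parse_preprocessing)


@dataclass
class SessionAnalysis:
    """Everything derived from one session in a single bundle."""

    session: ParsedSession
    entries: List[JoinedMicrograph]
    qualities: Dict[str, MicrographQuality]
    summary: SessionSummary
    preproc: Optional[PreprocResults] = None
    unmatched: List[str] = field(default_factory=list)

    @property
    def have_preprocessing(self) -> bool:
        return self.preproc is not None


def default_processed_dir(session_root: Path) -> Path:
    return Path(session_root) / "processed" / "raw" / "relion"


def analyze_session(session_root: Path | str,
                    processed_dir: Optional[Path | str] = None,
                    address_map: AddressMap = SYNTHETIC_ADDRESS_MAP,
                    params: MetricParameters = MetricParameters(),
                    ) -> SessionAnalysis:
    """Parse a session (and its preprocessing, when present) and reduce it.

    ``processed_dir`` defaults to ``<session>/processed/raw/relion``; an
    absent or empty directory simply yields an analysis without quality
    metrics.
    """
    session = parse_session(session_root, address_map)
    if processed_dir is None:
        candidate = default_processed_dir(session.root)
        processed_dir = candidate if candidate.is_dir() and any(candidate.iterdir()) \
            else None

    preproc = None
    unmatched: List[str] = []
    if processed_dir is not None:
        preproc = parse_preprocessing(processed_dir)
        joined = join_to_session(session.records, preproc)
        entries = joined.entries
        unmatched = joined.unmatched
    else:
        entries = [JoinedMicrograph(record=r) for r in session.records]

    preset = session.preset("acquisition")
    qualities = compute_all_qualities(entries, preset, params) if preproc else {}
    summary = summarize_session(entries, session.config, preset, qualities,
                                n_targeted_holes=len(session.hole_images) or None)
    return SessionAnalysis(session=session, entries=entries, qualities=qualities,
                           summary=summary, preproc=preproc, unmatched=unmatched)
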
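"""Structured findings shared by the validator and the metadata checks."""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass
from typing import Iterable


class Severity(str, enum.Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"


@dataclass(frozen=True)
class Finding:
    """One validation finding.

    ``code`` is a stable identifier from the rule registry; ``location`` is
    the offending entry location, or ``""`` when the finding concerns the
    archive as a whole.
    """

    severity: Severity
    code: str
    location: str
    message: str


def findings_to_json(findings: Iterable[Finding]) -> str:
    """Serialize findings as a JSON array (one object per finding)."""
    return json.dumps(
        [
            {**asdict(f), "severity": f.severity.value}
            for f in findings
        ],
        indent=2,
    )


def format_findings(findings: Iterable[Finding]) -> str:
    """Line-oriented text rendering: ``severity code [location]: message``."""
    lines = []
    for f in findings:
        where = f" [{f.location}]" if f.location else ""
        lines.append(f"{f.severity.value} {f.code}{where}: {f.message}")
    return "\n".join(lines)
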
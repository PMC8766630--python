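"""Projects: content-addressed, per-stage status tracking for pipeline runs."""

from __future__ import annotations

import enum
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path


class StageStatus(str, enum.Enum):
    PENDING = "pending"
    RUNNING = "running"
    DONE = "done"
    FAILED = "failed"


STAGES = (
    "segmentation",
    "geometry",
    "mesh",
    "simulation",
    "postprocessing",
)

EMPTY_SET_ID = "empty"


def content_hash(files=(), data: dict | None = None) -> str:
    """Order-independent SHA-256 digest over file contents (and config).

    The per-file digests are sorted before the final hash, so the id does
    not depend on the order in which files are listed.  An empty input
    set maps to the sentinel id ``"empty"``.
    """
    digests = []
    for f in files:
        p = Path(f)
        if not p.is_file():
            raise ValueError(f"unreadable file: {f}")
        digests.append(hashlib.sha256(p.read_bytes()).hexdigest())
    if data is not None:
        digests.append(
            hashlib.sha256(
                json.dumps(data, sort_keys=True, default=str).encode()
            ).hexdigest()
        )
    if not digests:
        return EMPTY_SET_ID
    outer = hashlib.sha256("".join(sorted(digests)).encode())
    return outer.hexdigest()[:16]


@dataclass
class Project:
    """One pipeline run, identified by the hash of its inputs."""

    project_id: str
    root: Path
    statuses: dict = field(default_factory=lambda: {s: StageStatus.PENDING for s in STAGES})
    config: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    @property
    def dir(self) -> Path:
        return Path(self.root) / self.project_id

    @property
    def status_file(self) -> Path:
        return self.dir / "status.json"

    def note(self, msg: str) -> None:
        self.log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def set_status(self, stage: str, status: StageStatus) -> None:
        order = [StageStatus.PENDING, StageStatus.RUNNING, StageStatus.DONE]
        cur = self.statuses[stage]
        if status != StageStatus.FAILED and cur != status:
            if cur == StageStatus.DONE and status != StageStatus.DONE:
                raise ValueError(f"stage {stage} cannot leave 'done'")
        self.statuses[stage] = status
        self.save()

    def save(self) -> None:
        self.dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "project_id": self.project_id,
            "statuses": {k: v.value for k, v in self.statuses.items()},
            "config": self.config,
            "log": self.log,
        }
        self.status_file.write_text(json.dumps(payload, indent=2, default=str))

    @classmethod
    def open(cls, root: str | Path, config: dict) -> "Project":
        pid = content_hash(data=config)
        proj = cls(project_id=pid, root=Path(root), config=config)
        if proj.status_file.is_file():
            saved = json.loads(proj.status_file.read_text())
            proj.statuses = {
                k: StageStatus(v) for k, v in saved["statuses"].items()
            }
            proj.log = saved.get("log", [])
        return proj
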
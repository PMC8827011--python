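"""Thin, optional REDCap API client.

The pipeline's contract boundary is the validated import CSV; this stub
exists only for sites that prefer pushing that CSV straight to their
project's API endpoint instead of using the web import tool.  It builds
the standard ``/api/`` form payload for the ``record`` import action.
Everything testable happens in :func:`build_import_payload`; the network
call itself is a two-line ``urllib`` POST and all package tests run
against files, never a live project.
"""

from __future__ import annotations

import urllib.parse
import urllib.request

from labharbor.harmonize import ImportTable

__all__ = ["build_import_payload", "RedcapClient"]


def build_import_payload(token: str, tbl: ImportTable) -> dict[str, str]:
    """The form fields REDCap's API expects for a CSV record import.

    ``overwriteBehavior=normal`` means blank cells do not erase stored
    data, matching the bulk-update workflow (routine re-pulls refresh
    lab values without clobbering manually abstracted fields).
    """
    return {
        "token": token,
        "content": "record",
        "action": "import",
        "format": "csv",
        "type": "flat",
        "overwriteBehavior": "normal",
        "data": tbl.to_csv(),
        "returnContent": "count",
        "returnFormat": "json",
    }


class RedcapClient:
    """Minimal API client: one project URL, one token, one import call."""

    def __init__(self, url: str, token: str):
        self.url = url
        self.token = token

    def import_table(self, tbl: ImportTable, timeout: float = 60.0) -> bytes:
        """POST a validated import table to the project API.

        Callers are expected to have run ``validate_import`` first; the
        server will reject nonconforming rows with its own error
        listing, which is returned verbatim.
        """
        payload = urllib.parse.urlencode(
            build_import_payload(self.token, tbl)
        ).encode()
        with urllib.request.urlopen(self.url, data=payload, timeout=timeout) as resp:
            return resp.read()
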
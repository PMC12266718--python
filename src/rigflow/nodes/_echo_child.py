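"""Echo test child for the external-process node.

Connects back to the managing worker on the endpoint named in argv,
performs the READY / parameter-record / ACK handshake, then appends every
subsequent line it receives to the log file named in its parameters.
Run as: ``python -m rigflow.nodes._echo_child <port>``.
"""

from __future__ import annotations

import json
import socket
import sys


def main() -> int:
    port = int(sys.argv[1])
    with socket.create_connection(("127.0.0.1", port), timeout=10.0) as sock:
        fh = sock.makefile("rwb")
        fh.write(b"READY\n")
        fh.flush()
        params = json.loads(fh.readline().decode("utf-8"))
        fh.write(b"ACK\n")
        fh.flush()
        log_path = params.get("log_path")
        log = open(log_path, "a") if log_path else None
        try:
            for line in fh:
                text = line.decode("utf-8").rstrip("\n")
                if text == "QUIT":
                    break
                if log is not None:
                    log.write(text + "\n")
                    log.flush()
        finally:
            if log is not None:
                log.close()
    return 0


if __name__ == "__main__":
    sys.exit(main())
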
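import sys
from pathlib import Path

# tests/helpers.py holds the brute-force oracles
sys.path.insert(0, str(Path(__file__).parent))
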
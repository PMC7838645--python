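(COL17A1 <= 7.226) and (NFKBIZ >= 10.687) => IL-17
(CCDC86 <= 9.636) and (NFKBIZ >= 10.454) => IL-17
(DTNA <= 7.176) and (NFKBIZ <= 10.496) => IL-13
(CCL11 >= 12.814) and (MAP3K8 <= 9.294) and (SLIT2 <= 11.423) => IL-13
(PPFIBP2 >= 9.582) => IL-13
(MAP3K8 >= 8.957) => IL-13 and IL-17
default => Control
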
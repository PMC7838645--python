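(GPR44 >= 7.200) and (ZC3H12A <= 8.211) => IL-13
(SEMA3A <= 9.623) and (NFKBIZ <= 10.612) => IL-13
(MYOM1 >= 7.527) and (MAP3K8 <= 9.269) => IL-13
(NFKBIZ <= 10.483) and (MAP3K8 <= 8.234) => Control
(LSS <= 10.932) => Control
(CCL26 <= 9.291) => IL-17
default => IL-13 and IL-17
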
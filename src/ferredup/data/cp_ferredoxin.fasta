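>CpFd 2[4Fe-4S] ferredoxin, Clostridium pasteurianum (mature chain, 55 aa)
AYKIADSCVSCGACASECPVNAISQGDSIFVIDADTCIDCGNCANVCPVGAPVQE
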
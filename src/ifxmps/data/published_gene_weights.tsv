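# Published 30-gene infliximab-response signature: Gene Weight per gene,
# direction relative to responders (up = higher in responders).
gene	weight	direction
IL13RA2	0.3404	down
TNFRSF11B	0.2082	down
STC1	0.3198	down
PROK2	0.3326	down
NAMPT	0.3178	down
PTGS2	0.0912	down
IL11	0.342	down
WNT5A	0.3351	down
TWIST1	0.3171	down
GLIS3	0.3627	down
IL6	0.4434	down
MGAM	0.3457	down
MME	0.4478	down
PDE4B	0.2839	down
CXCL8	0.3087	down
CEMIP	0.3602	down
TREM1	0.3959	down
IL1B	0.3385	down
INHBA	0.2298	down
ACOD1	0.4049	down
C10orf99	0.3389	up
IL24	0.2098	down
TFPI2	0.4268	down
CCR1	0.3559	down
CSF2RB	0.2966	down
ADH1C	0.0852	up
CXCL11	0.4086	down
PI15	0.2851	down
GBP5	0.1814	down
CXCR2	0.1764	down
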
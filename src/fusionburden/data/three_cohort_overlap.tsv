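fusion	FFPE_Bx	FF_RP	TCGA_PRAD	known
ERG(30,742),NCRNA00114(46,499)::ERG	1	1	1	FALSE
AMACR::AMACR	1	1	1	FALSE
FSIP1::RP11-624L4.1	1	1	1	FALSE
MBTPS2(33,120),LL0XNC01-39B3.1(20,917)::SMS	1	1	1	FALSE
AMBRA1::CKAP5	1	1	0	FALSE
THBS1::RP11-624L4.1	1	1	0	FALSE
LINC00506(49,329),MIR4795(19,791)::CHMP2B	1	1	0	FALSE
RP11-159H20.3(25,945),FOXB2(602)::PRUNE2	1	1	0	FALSE
RP11-597A11.11::RP11-597A11.1	1	1	0	FALSE
AC004921.2(27,972),PTPN12(47,164)::GSAP	1	1	0	FALSE
RP11-356O9.1::ETV1	1	0	1	FALSE
PTEN::RP11-380G5.4(8171),RP11-129G17.2(201,135)	1	0	1	FALSE
PTEN::RNLS	1	0	1	FALSE
MAPKAPK5::ACAD10	1	0	1	FALSE
ACPP::CPNE4	1	0	1	FALSE
CTC-340A15.2::CTC-535M15.2	1	0	1	FALSE
PLPP1::SKIV2L2	1	0	1	FALSE
SCHLAP1::UBE2E3	1	0	1	FALSE
RP11-17A19.1::KCTD1	1	0	1	FALSE
ZFHX3::AC004158.2	1	0	1	FALSE
RP11-356O9.1::MIPOL1	0	1	1	FALSE
TTC6::SLC25A21	0	1	1	FALSE
RP11-599B13.3::ETV1	0	1	1	FALSE
C1QTNF3-AMACR::AMACR	0	1	1	FALSE
RP11-492D6.3::RP11-810K23.8(24,509),RP11-810K23.6(7644)	0	1	1	FALSE
SLC45A3::ELK4	1	1	1	TRUE
TMPRSS2::ERG	1	1	1	TRUE
TMPRSS2::ETV4	1	1	1	TRUE
TTC6::MIPOL1	1	1	1	TRUE
SLC45A3::ERG	1	1	1	TRUE
ERG::TMPRSS2	1	0	1	TRUE
PMEPA1::ETV4	1	0	1	TRUE
SLC45A3::ETV1	1	0	1	TRUE
IQSEC1::SCCPDH	1	0	1	TRUE
GPATCH8::PYY	1	0	1	TRUE
PDZRN3::EIF4E3	0	1	1	TRUE
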
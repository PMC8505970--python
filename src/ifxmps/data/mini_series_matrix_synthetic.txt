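!Series_title	"Synthetic miniature series-matrix fixture (5 genes x 4 samples)"
!Sample_title	"S1"	"S2"	"S3"	"S4"
!Sample_geo_accession	"GSM0001"	"GSM0002"	"GSM0003"	"GSM0004"
!Sample_characteristics_ch1	"response: responder"	"response: responder"	"response: non_responder"	"response: non_responder"
!series_matrix_table_begin
"ID_REF"	"S1"	"S2"	"S3"	"S4"
"IL6"	5.10	4.90	7.20	7.40
"MME"	6.00	6.20	8.10	7.90
"PTGS2"	4.50	4.70	6.60	6.40
"ADH1C"	9.10	8.90	7.00	7.20
"ACTB"	10.00	10.10	9.90	10.05
!series_matrix_table_end
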
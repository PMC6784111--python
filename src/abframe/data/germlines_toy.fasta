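>KV3-20L synthetic germline V gene (toy reference set)
EIVLTQSPSSLSASVGDRVTITCRASQSVSSYLAWYQQKPGKAPKLLIYGASSRATGVPSRFSGSGSGTDFTLTISSLEPEDFATYYCQQYGSSP
>KV1-39L synthetic germline V gene (toy reference set)
DIQMSQSPDSLSLSVGDKVTISCRASQSVNSYLAWYQQKPGQAPELLIYGASSRATGVPSRFTGSGSGTEFTLSISSLQPEDFATYYCQQYGSSP
>KV1-5L synthetic germline V gene (toy reference set)
DIQMTQTPSILSATVGERVTLTCRASQDVSSYLAWYQQKSGKSPKRLIYGASSRATGVPARFSGSGSGTDFSLTISSLQPEDFATYYCQQYGSSP
>KV2-28L synthetic germline V gene (toy reference set)
DVQMTESTSSMSASPGDRATITCRASQSVSNYLAWYLQKPSKAPKLLIYGASSRATGIPSRFSGSGAGTDFTLTISNLQPEDFATYYCQQYGSSP
>KV4-1L synthetic germline V gene (toy reference set)
EIQMSQSPSSLAASVEDRVSITCRASQSVSSYVAWFQQKPGKAVKLLVYGASSRATGVPSKFSGSGSGSDFTLTISSLQAEDFATYYCQQYGSSP
>KV6-21L synthetic germline V gene (toy reference set)
DIVMTQSPATLSTSVGDRVTITCRASQSGSSYLAWYQHKPGKAPKLWIYGASSRATGVASRFSASGSGTDFTLTLSSLQPEEFATFYCQQYGSSP
>HV3-23L synthetic germline V gene (toy reference set)
EVQLLESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYDRGG
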
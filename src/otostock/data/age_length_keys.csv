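group,bin_lower,bin_upper,age,count
females,16.00,18.18,0,4
females,16.00,18.18,2,1
females,18.18,20.36,0,2
females,18.18,20.36,1,6
females,18.18,20.36,2,3
females,20.36,22.55,0,1
females,20.36,22.55,1,1
females,20.36,22.55,2,50
females,20.36,22.55,3,2
females,22.55,24.73,0,1
females,22.55,24.73,2,96
females,22.55,24.73,3,20
females,24.73,26.91,2,9
females,24.73,26.91,3,76
females,24.73,26.91,4,7
females,26.91,29.09,2,1
females,26.91,29.09,3,34
females,26.91,29.09,4,37
females,26.91,29.09,5,25
females,29.09,31.27,3,1
females,29.09,31.27,4,1
females,29.09,31.27,5,42
females,29.09,31.27,6,45
females,29.09,31.27,7,17
females,31.27,33.45,5,1
females,31.27,33.45,6,4
females,31.27,33.45,7,5
females,31.27,33.45,8,8
females,31.27,33.45,9,29
females,31.27,33.45,10,3
females,33.45,35.64,9,3
females,33.45,35.64,10,8
females,33.45,35.64,11,4
females,35.64,37.82,11,9
females,37.82,40.00,11,1
females,37.82,40.00,12,3
males,16.00,18.18,0,1
males,16.00,18.18,1,1
males,16.00,18.18,2,2
males,18.18,20.36,0,1
males,18.18,20.36,1,7
males,18.18,20.36,2,8
males,20.36,22.55,2,49
males,20.36,22.55,3,3
males,22.55,24.73,2,100
males,22.55,24.73,3,26
males,22.55,24.73,4,1
males,24.73,26.91,2,11
males,24.73,26.91,3,102
males,24.73,26.91,4,6
males,26.91,29.09,3,24
males,26.91,29.09,4,58
males,26.91,29.09,5,33
males,29.09,31.27,4,1
males,29.09,31.27,5,33
males,29.09,31.27,6,28
males,29.09,31.27,7,6
males,29.09,31.27,8,2
males,29.09,31.27,9,1
males,31.27,33.45,5,1
males,31.27,33.45,6,1
males,31.27,33.45,7,9
males,31.27,33.45,8,6
males,31.27,33.45,9,21
males,31.27,33.45,10,3
males,33.45,35.64,9,1
males,33.45,35.64,10,6
males,35.64,37.82,11,6
males,35.64,37.82,12,1
males,37.82,40.00,11,3
males,37.82,40.00,12,1
males,40.00,42.18,12,1
celestun,16.00,18.18,0,7
celestun,16.00,18.18,1,2
celestun,18.18,20.36,0,2
celestun,18.18,20.36,1,11
celestun,18.18,20.36,2,16
celestun,20.36,22.55,2,70
celestun,20.36,22.55,3,6
celestun,22.55,24.73,2,118
celestun,22.55,24.73,3,33
celestun,24.73,26.91,2,9
celestun,24.73,26.91,3,29
celestun,24.73,26.91,4,3
celestun,26.91,29.09,3,8
celestun,26.91,29.09,4,13
celestun,26.91,29.09,5,3
celestun,29.09,31.27,4,1
celestun,29.09,31.27,5,1
celestun,29.09,31.27,6,3
celestun,31.27,33.45,7,1
celestun,31.27,33.45,9,2
dzilam,18.18,20.36,1,1
dzilam,20.36,22.55,2,20
dzilam,20.36,22.55,3,3
dzilam,22.55,24.73,2,26
dzilam,22.55,24.73,3,10
dzilam,24.73,26.91,2,7
dzilam,24.73,26.91,3,40
dzilam,24.73,26.91,4,2
dzilam,26.91,29.09,3,29
dzilam,26.91,29.09,4,39
dzilam,26.91,29.09,5,20
dzilam,29.09,31.27,4,5
dzilam,29.09,31.27,5,46
dzilam,29.09,31.27,6,43
dzilam,29.09,31.27,7,10
dzilam,29.09,31.27,8,1
dzilam,31.27,33.45,5,4
dzilam,31.27,33.45,6,4
dzilam,31.27,33.45,7,13
dzilam,31.27,33.45,8,9
dzilam,31.27,33.45,9,31
dzilam,33.45,35.64,9,2
dzilam,33.45,35.64,10,9
dzilam,33.45,35.64,11,2
dzilam,35.64,37.82,10,1
dzilam,35.64,37.82,11,6
dzilam,37.82,40.00,11,2
dzilam,37.82,40.00,12,5
dzilam,40.00,42.18,11,1
rio_lagartos,20.36,22.55,2,14
rio_lagartos,20.36,22.55,3,4
rio_lagartos,22.55,24.73,2,45
rio_lagartos,22.55,24.73,3,11
rio_lagartos,24.73,26.91,2,6
rio_lagartos,24.73,26.91,3,92
rio_lagartos,24.73,26.91,4,8
rio_lagartos,26.91,29.09,3,18
rio_lagartos,26.91,29.09,4,43
rio_lagartos,26.91,29.09,5,29
rio_lagartos,29.09,31.27,5,30
rio_lagartos,29.09,31.27,6,26
rio_lagartos,29.09,31.27,7,7
rio_lagartos,29.09,31.27,8,1
rio_lagartos,29.09,31.27,9,2
rio_lagartos,31.27,33.45,5,1
rio_lagartos,31.27,33.45,6,2
rio_lagartos,31.27,33.45,7,6
rio_lagartos,31.27,33.45,8,5
rio_lagartos,31.27,33.45,9,16
rio_lagartos,31.27,33.45,10,5
rio_lagartos,33.45,35.64,9,2
rio_lagartos,33.45,35.64,10,6
rio_lagartos,33.45,35.64,11,6
rio_lagartos,35.64,37.82,11,6
rio_lagartos,35.64,37.82,12,1
rio_lagartos,37.82,40.00,11,2
rio_lagartos,40.00,42.18,12,1
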